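"""Model evaluation: Harrell's C-index and rank-based model comparison.

The C-index scores a risk ranking against right-censored outcomes; the
Friedman test checks whether m models differ over n repeated runs via
their per-run performance ranks, and the Nemenyi post-hoc z locates the
differing pairs.  A paired Wilcoxon signed-rank comparison (delegated to
scipy) covers two-model contrasts.

C-index pair rules (fixed here and locked by exhaustive-enumeration
tests): a pair is permissible when the shorter observed time belongs to an
event, i.e. (a) t_i < t_j with subject i an event, or (b) t_i == t_j with
i an event and j censored (the censored subject survived at least t_i).
Pairs tied in time with both subjects events are excluded.  A permissible
pair scores 1 when the shorter-surviving subject has the strictly higher
risk, 1/2 on tied risks, else 0.  This matches the convention of the
widely used survival-analysis implementations.
"""

from __future__ import annotations

from dataclasses import dataclass
from string import ascii_uppercase

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "harrell_c_index",
    "rank_matrix",
    "friedman_statistic",
    "nemenyi_z",
    "nemenyi_critical_value",
    "compare_models",
    "ModelComparison",
]


def harrell_c_index(times, events, risks) -> float:
    """Harrell's concordance index in [0, 1].

    Fraction of permissible pairs (see module docstring) in which the
    subject with the shorter survival has the higher predicted risk; tied
    risks count 1/2.  Raises ``ValueError`` when no permissible pair
    exists (e.g. all subjects censored).
    """
    t = np.asarray(times, float)
    d = np.asarray(events, int).astype(bool)
    r = np.asarray(risks, float)
    if not (t.shape == d.shape == r.shape):
        raise ValueError("times, events and risks must have equal length")
    shorter_event = (t[:, None] < t[None, :]) & d[:, None]
    tied_vs_censored = (t[:, None] == t[None, :]) & d[:, None] & ~d[None, :]
    permissible = shorter_event | tied_vs_censored
    n_pairs = permissible.sum()
    if n_pairs == 0:
        raise ValueError("no permissible pairs: concordance is undefined")
    concordant = (permissible & (r[:, None] > r[None, :])).sum()
    tied = (permissible & (r[:, None] == r[None, :])).sum()
    return float((concordant + 0.5 * tied) / n_pairs)


def rank_matrix(scores) -> np.ndarray:
    """Per-run performance ranks (higher score -> higher rank; ties averaged).

    ``scores`` is (n runs, m models); every row of the result sums to
    m(m+1)/2.
    """
    scores = np.atleast_2d(np.asarray(scores, float))
    return np.apply_along_axis(stats.rankdata, 1, scores)


def friedman_statistic(ranks) -> float:
    """Friedman test statistic from a (n runs, m models) rank matrix.

    ``FT = 12 / (n m (m+1)) * sum_j (sum_i r_ij)^2 - 3 n (m+1)``; zero iff
    every model has the same rank total.  Under the null it is
    asymptotically chi-squared with m - 1 degrees of freedom.
    """
    R = np.atleast_2d(np.asarray(ranks, float))
    n, m = R.shape
    if n < 2 or m < 2:
        raise ValueError("need at least 2 runs and 2 models")
    expected_row = m * (m + 1) / 2
    if not np.allclose(R.sum(axis=1), expected_row):
        raise ValueError("each row of ranks must sum to m(m+1)/2")
    col_sums = R.sum(axis=0)
    return float(12.0 / (n * m * (m + 1)) * (col_sums ** 2).sum() - 3.0 * n * (m + 1))


def nemenyi_z(mean_rank_1: float, mean_rank_2: float, n: int, m: int) -> float:
    """Nemenyi post-hoc statistic ``z = (R1 - R2) / sqrt(m(m+1) / (6n))``."""
    return float((mean_rank_1 - mean_rank_2) / np.sqrt(m * (m + 1) / (6.0 * n)))


def nemenyi_critical_value(alpha: float = 0.05, m: int = 2) -> float:
    """Reference critical value ``q_alpha(m, inf) / sqrt(2)``.

    Based on the studentized range distribution; supplied as a helper
    only — comparisons accept a user-chosen critical value.
    """
    return float(stats.studentized_range.ppf(1.0 - alpha, m, np.inf) / np.sqrt(2.0))


@dataclass
class ModelComparison:
    """Friedman/Nemenyi/Wilcoxon comparison of m models over n runs."""

    labels: list
    ranks: np.ndarray
    mean_ranks: np.ndarray
    friedman: float
    friedman_pvalue: float
    nemenyi: pd.DataFrame
    wilcoxon_pvalues: pd.DataFrame
    significant: pd.DataFrame
    critical_value: float

    def summary(self) -> str:
        n, m = self.ranks.shape
        lines = [
            f"Model comparison over {n} runs, {m} models",
            "",
            "Mean ranks (higher = better performance):",
        ]
        for lab, r in zip(self.labels, self.mean_ranks):
            lines.append(f"  {lab}: {r:.4f}")
        lines += [
            "",
            f"Friedman statistic FT = {self.friedman:.4f} "
            f"(p = {self.friedman_pvalue:.4g})",
            f"Nemenyi critical value (reference) = {self.critical_value:.4f}",
            "",
            "Pairwise Nemenyi z (row minus column):",
            self.nemenyi.round(4).to_string(),
            "",
            "Paired Wilcoxon signed-rank p-values (NaN = degenerate pair):",
            self.wilcoxon_pvalues.map(
                lambda v: "" if np.isnan(v) else f"{v:.4g}"
            ).to_string(),
        ]
        return "\n".join(lines)


def compare_models(score_matrix, labels=None, alpha: float = 0.05,
                   critical_value: float | None = None) -> ModelComparison:
    """Full model-comparison report from a (runs, models) score matrix.

    Scores are ranked per run (higher score = higher rank), the Friedman
    statistic and its chi-squared p-value computed, all pairwise Nemenyi z
    values tabulated, and paired Wilcoxon signed-rank tests run per pair
    (flagged NaN when the pair is degenerate, i.e. identical scores on
    every run).  Pairs whose |z| exceeds ``critical_value`` (default: the
    studentized-range reference at ``alpha``) are flagged significant.
    Model labels default to A, B, C, ...
    """
    scores = np.atleast_2d(np.asarray(score_matrix, float))
    n, m = scores.shape
    if n < 2 or m < 2:
        raise ValueError("need at least 2 runs and 2 models")
    if labels is None:
        labels = [ascii_uppercase[j % 26] for j in range(m)]
    labels = list(labels)
    ranks = rank_matrix(scores)
    mean_ranks = ranks.mean(axis=0)
    ft = friedman_statistic(ranks)
    pvalue = float(stats.chi2.sf(ft, m - 1))
    if critical_value is None:
        critical_value = nemenyi_critical_value(alpha, m)
    z = np.zeros((m, m))
    w = np.full((m, m), np.nan)
    for a in range(m):
        for b in range(m):
            if a == b:
                continue
            z[a, b] = nemenyi_z(mean_ranks[a], mean_ranks[b], n, m)
            diff = scores[:, a] - scores[:, b]
            if np.any(diff != 0):
                w[a, b] = stats.wilcoxon(scores[:, a], scores[:, b]).pvalue
    zdf = pd.DataFrame(z, index=labels, columns=labels)
    wdf = pd.DataFrame(w, index=labels, columns=labels)
    sig = pd.DataFrame(np.abs(z) > critical_value, index=labels, columns=labels)
    np.fill_diagonal(sig.values, False)
    return ModelComparison(
        labels=labels,
        ranks=ranks,
        mean_ranks=mean_ranks,
        friedman=ft,
        friedman_pvalue=pvalue,
        nemenyi=zdf,
        wilcoxon_pvalues=wdf,
        significant=sig,
        critical_value=float(critical_value),
    )
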