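"""Out-of-bag permutation variable importance: mean C-index decrease.

For each ensemble member, the C-index of its risk predictions on its own
out-of-bag (OOB) subjects is computed before and after permuting one
original covariate's values among those OOB subjects; the importance of
the covariate is the average drop over members, on a x100 (percentage
point) scale:

    VI_v = (100 / L) * sum_j (C_j - C_j_permuted)

The permutation happens in the original covariate space, before the
member's rotation is applied — so a member whose random remainder set
contains the covariate contributes exactly zero (its rotation has a zero
row there).  Members whose OOB set admits no permissible concordance pair
are skipped and the divisor reduced accordingly.  An unassociated
covariate has importance near zero; associated covariates degrade the
OOB ranking when permuted and score positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import SurvivalDataset
from .ensemble import RotSFModel, _member_risk
from .evaluation import harrell_c_index

__all__ = [
    "VariableImportanceResult",
    "mean_cindex_decrease",
    "variable_importances",
    "rank_importances",
    "plot_importances",
]


@dataclass
class VariableImportanceResult:
    """Per-covariate mean C-index decrease (x100 scale).

    ``values`` maps each original covariate name to its importance;
    ``member_decreases`` optionally retains the per-member samples for
    dispersion reporting; ``n_replicates`` is the number of permutation
    replicates averaged per member.
    """

    values: pd.Series
    member_decreases: dict
    n_replicates: int = 1

    def table(self) -> pd.DataFrame:
        order = self.values.sort_values(ascending=False, kind="stable")
        return pd.DataFrame({
            "covariate": order.index,
            "importance": order.to_numpy(),
            "rank": np.arange(1, order.size + 1),
        })


def _resolve_variable(model: RotSFModel, variable) -> int:
    if isinstance(variable, str):
        if variable not in model.names:
            raise ValueError(f"unknown covariate {variable!r}")
        return model.names.index(variable)
    v = int(variable)
    if not 0 <= v < model.p:
        raise ValueError(f"covariate index {v} out of range [0, {model.p})")
    return v


def mean_cindex_decrease(model: RotSFModel, dataset: SurvivalDataset, variable,
                         rng=None, n_replicates: int = 1,
                         permute_fn=None, return_samples: bool = False):
    """Mean OOB C-index decrease for one covariate (x100 scale).

    ``variable`` is a covariate name or zero-based index.  ``permute_fn``
    (signature ``(rng, size) -> index array``) overrides the permutation
    draw — useful for diagnostics such as forcing the identity
    permutation, which must yield exactly zero.  Only each member's OOB
    rows are ever permuted; in-bag rows are untouched.
    """
    if not model.members:
        raise ValueError("model has no fitted members")
    v = _resolve_variable(model, variable)
    rng = np.random.default_rng(rng)
    if permute_fn is None:
        permute_fn = lambda r, size: r.permutation(size)
    decreases = []
    for i, member in enumerate(model.members):
        mask = model.oob_mask(i)
        if mask.sum() < 2:
            continue
        t = dataset.times[mask]
        e = dataset.events[mask]
        X_oob = dataset.covariates[mask]
        try:
            c_before = harrell_c_index(t, e, _member_risk(member, X_oob, model.grid))
        except ValueError:  # no permissible pairs in this OOB set
            continue
        drop = 0.0
        for _ in range(n_replicates):
            perm = np.asarray(permute_fn(rng, mask.sum()))
            X_perm = X_oob.copy()
            X_perm[:, v] = X_oob[perm, v]
            c_after = harrell_c_index(t, e, _member_risk(member, X_perm, model.grid))
            drop += c_before - c_after
        decreases.append(drop / n_replicates)
    if not decreases:
        raise ValueError("no member had a usable OOB set")
    vi = 100.0 * float(np.mean(decreases))
    if return_samples:
        return vi, np.asarray(decreases)
    return vi


def variable_importances(model: RotSFModel, dataset: SurvivalDataset,
                         rng=None, n_replicates: int = 1) -> VariableImportanceResult:
    """Mean C-index decrease for every original covariate."""
    rng = np.random.default_rng(rng)
    values = {}
    samples = {}
    for v, name in enumerate(model.names):
        vi, per_member = mean_cindex_decrease(
            model, dataset, v, rng=rng, n_replicates=n_replicates,
            return_samples=True,
        )
        values[name] = vi
        samples[name] = per_member
    return VariableImportanceResult(pd.Series(values), samples, n_replicates)


def rank_importances(model: RotSFModel, dataset: SurvivalDataset,
                     top_k: int | None = None, rng=None,
                     n_replicates: int = 1) -> pd.DataFrame:
    """Covariates sorted by decreasing importance (ties keep column order).

    Returns the top ``top_k`` rows of the (covariate, importance, rank)
    table; ``top_k=None`` or ``top_k >= p`` gives the full ordering.
    """
    result = variable_importances(model, dataset, rng=rng,
                                  n_replicates=n_replicates)
    table = result.table()
    if top_k is not None:
        table = table.head(top_k).reset_index(drop=True)
    return table


def plot_importances(table: pd.DataFrame, path=None, ax=None):
    """Horizontal bar plot of an importance table (most important on top)."""
    import matplotlib
    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.4 * len(table) + 1.5))
    rows = table.iloc[::-1]
    ax.barh(rows["covariate"], rows["importance"], color="#4878a8")
    ax.set_xlabel("mean C-index decrease (x100)")
    ax.set_title("Variable importance")
    if path is not None:
        ax.figure.tight_layout()
        ax.figure.savefig(path, dpi=150)
        plt.close(ax.figure)
    return ax
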