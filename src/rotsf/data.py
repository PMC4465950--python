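"""Survival dataset container and delimited-text I/O.

A dataset holds one row per subject: an observed follow-up time
``tau = min(U, C)`` (event time ``U``, censoring time ``C``), an event
indicator ``delta = I(U <= C)`` (1 = event observed, 0 = right-censored),
and a numeric covariate matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SurvivalDataset", "read_csv", "write_csv", "dataset_summary"]


@dataclass(frozen=True)
class SurvivalDataset:
    """Right-censored survival data.

    Parameters
    ----------
    times : ndarray, shape (n,)
        Observed follow-up times, strictly positive.
    events : ndarray, shape (n,)
        Event indicators in {0, 1}; 1 means the event was observed.
    covariates : ndarray, shape (n, p)
        Numeric covariate matrix without missing values.
    names : tuple of str
        Covariate labels, length p.
    """

    times: np.ndarray
    events: np.ndarray
    covariates: np.ndarray
    names: tuple = field(default=())

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        events = np.asarray(self.events, dtype=int)
        X = np.atleast_2d(np.asarray(self.covariates, dtype=float))
        if times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        n = times.shape[0]
        if n < 2:
            raise ValueError("need at least two subjects")
        if events.shape != (n,) or X.shape[0] != n:
            raise ValueError("times, events and covariates must agree in length")
        if not np.all(times > 0):
            raise ValueError("all follow-up times must be strictly positive")
        if not np.isin(events, (0, 1)).all():
            raise ValueError("event indicators must be 0 or 1")
        if events.sum() < 1:
            raise ValueError("dataset must contain at least one event")
        if not np.isfinite(X).all():
            raise ValueError("covariates must be finite (no missing values)")
        names = tuple(self.names) if len(self.names) else tuple(
            f"x{j + 1}" for j in range(X.shape[1])
        )
        if len(names) != X.shape[1]:
            raise ValueError("names must match the number of covariates")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "events", events)
        object.__setattr__(self, "covariates", X)
        object.__setattr__(self, "names", names)

    @property
    def n(self) -> int:
        return self.times.shape[0]

    @property
    def p(self) -> int:
        return self.covariates.shape[1]

    def subset(self, idx) -> "SurvivalDataset":
        """Row subset / bootstrap view (``idx`` may repeat indices)."""
        return SurvivalDataset(
            self.times[idx], self.events[idx], self.covariates[idx], self.names
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.covariates, columns=list(self.names))
        df.insert(0, "status", self.events)
        df.insert(0, "time", self.times)
        return df


def read_csv(path, time_col: str = "time", status_col: str = "status") -> SurvivalDataset:
    """Read a survival dataset from delimited text.

    Expects a header row with a follow-up-time column, a 0/1 event-status
    column (1 = event), and numeric covariate columns; column names are
    remappable via ``time_col`` / ``status_col`` for external exports.
    """
    df = pd.read_csv(path)
    for col in (time_col, status_col):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    covs = [c for c in df.columns if c not in (time_col, status_col)]
    return SurvivalDataset(
        df[time_col].to_numpy(float),
        df[status_col].to_numpy(int),
        df[covs].to_numpy(float),
        tuple(covs),
    )


def write_csv(dataset: SurvivalDataset, path) -> None:
    dataset.to_frame().to_csv(path, index=False)


def dataset_summary(dataset: SurvivalDataset) -> dict:
    """Per-dataset summary row: size, dimension, censoring count and rate.

    The censoring rate is the censored fraction as a percentage rounded to
    two decimals (e.g. 257 censored of 418 -> 61.48).
    """
    n = dataset.n
    n_cens = int(n - dataset.events.sum())
    return {
        "n": n,
        "p": dataset.p,
        "n_censored": n_cens,
        "censoring_rate_pct": round(100.0 * n_cens / n, 2),
    }
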