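"""Survival CART base learner.

A single tree recursively partitions subjects by maximising the absolute
standardized two-group log-rank statistic over exhaustive (variable,
threshold) candidates; each leaf stores the Nelson-Aalen cumulative hazard
function (CHF) of its subjects evaluated on the tree's grid of unique
training event times.

Conventions (fixed for determinism):

* splits send ``x[var] <= threshold`` to the left child; thresholds are
  midpoints of consecutive distinct observed values;
* censored subjects tied with an event time remain at risk at that time;
* a candidate split whose log-rank variance is zero carries no information
  and is encoded as NaN — it is never preferred over any finite statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import SurvivalDataset

__all__ = [
    "SurvivalTree",
    "logrank_split_statistic",
    "find_best_split",
    "nelson_aalen_chf",
    "grow_tree",
    "predict_tree_chf",
    "predict_chf_matrix",
]

_EPS = 1e-12


def _event_tables(times, events):
    """Unique event times with event counts d(u) and at-risk counts Y(u)."""
    grid = np.unique(times[events == 1])
    at_risk = times[:, None] >= grid[None, :]
    dying = (times[:, None] == grid[None, :]) & (events == 1)[:, None]
    return grid, at_risk.astype(float), dying.astype(float)


def _logrank_from_membership(memb, at_risk, dying):
    """Standardized log-rank statistics for each membership row.

    ``memb`` is (T, n); returns (stat, n_left) with NaN where the
    hypergeometric variance vanishes.
    """
    Y = at_risk.sum(axis=0)
    d = dying.sum(axis=0)
    Y1 = memb @ at_risk
    d1 = memb @ dying
    with np.errstate(invalid="ignore", divide="ignore"):
        expected = d * Y1 / Y
        frac = Y1 / Y
        # hypergeometric variance of d1 at each event time
        corr = np.where(Y > 1, (Y - d) / np.maximum(Y - 1, 1), 0.0)
        var = (d * frac * (1.0 - frac) * corr).sum(axis=1)
        observed_minus_expected = (d1 - expected).sum(axis=1)
        stat = np.where(var > _EPS, observed_minus_expected / np.sqrt(var), np.nan)
    return stat, memb.sum(axis=1)


def logrank_split_statistic(times, events, membership) -> float:
    """Standardized two-group log-rank statistic.

    Sum over distinct event times of observed-minus-expected events in the
    group flagged by ``membership``, divided by the square root of the
    summed hypergeometric variance.  Antisymmetric under swapping group
    labels.  Returns NaN (the "no information" sentinel) when the variance
    is zero, e.g. when one group covers every risk set.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    memb = np.asarray(membership, float).reshape(1, -1)
    n1 = memb.sum()
    if n1 == 0 or n1 == memb.size:
        raise ValueError("membership must define two non-empty groups")
    if events.sum() == 0:
        raise ValueError("at least one event is required")
    _, at_risk, dying = _event_tables(times, events)
    stat, _ = _logrank_from_membership(memb, at_risk, dying)
    return float(stat[0])


def find_best_split(dataset: SurvivalDataset, subjects=None, min_node_size: int = 6):
    """Exhaustive best log-rank split for one node.

    Scans midpoints of consecutive distinct values of every covariate and
    returns ``(variable, threshold)`` maximising the absolute standardized
    log-rank statistic subject to both children holding at least
    ``min_node_size`` subjects, or ``None`` if no admissible candidate
    exists (ties broken by lowest variable index, then lowest threshold).
    """
    if subjects is None:
        subjects = np.arange(dataset.n)
    times = dataset.times[subjects]
    events = dataset.events[subjects]
    X = dataset.covariates[subjects]
    if events.sum() == 0 or times.size < 2 * min_node_size:
        return None
    _, at_risk, dying = _event_tables(times, events)
    best = (np.nan, -1, np.nan)  # |stat|, var, threshold
    for v in range(X.shape[1]):
        x = X[:, v]
        distinct = np.unique(x)
        if distinct.size < 2:
            continue
        thresholds = 0.5 * (distinct[:-1] + distinct[1:])
        memb = (x[None, :] <= thresholds[:, None]).astype(float)
        stat, n_left = _logrank_from_membership(memb, at_risk, dying)
        ok = (
            np.isfinite(stat)
            & (n_left >= min_node_size)
            & (times.size - n_left >= min_node_size)
        )
        if not ok.any():
            continue
        a = np.where(ok, np.abs(stat), -np.inf)
        k = int(np.argmax(a))  # first maximum -> lowest threshold
        if not np.isfinite(best[0]) or a[k] > best[0] + _EPS:
            best = (a[k], v, float(thresholds[k]))
    if best[1] < 0:
        return None
    return best[1], best[2]


def nelson_aalen_chf(times, events, grid) -> np.ndarray:
    """Nelson-Aalen cumulative hazard evaluated on ``grid``.

    ``CHF(t) = sum_{event times u <= t} d(u) / Y(u)`` with d(u) events and
    Y(u) subjects at risk at u; right-continuous, non-decreasing, zero
    before the first event.  With no events the CHF is identically zero.
    """
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    grid = np.asarray(grid, float)
    event_times, counts = np.unique(times[events == 1], return_counts=True)
    if event_times.size == 0:
        return np.zeros_like(grid)
    at_risk = (times[:, None] >= event_times[None, :]).sum(axis=0)
    cumhaz = np.cumsum(counts / at_risk)
    idx = np.searchsorted(event_times, grid, side="right")
    return np.concatenate(([0.0], cumhaz))[idx]


@dataclass
class _Node:
    n_samples: int
    var: int = -1
    threshold: float = np.nan
    left: int = -1
    right: int = -1
    chf: np.ndarray | None = None

    @property
    def is_leaf(self) -> bool:
        return self.var < 0


@dataclass
class SurvivalTree:
    """Recursive survival partition with Nelson-Aalen leaf CHFs.

    ``nodes[0]`` is the root; internal nodes route ``x[var] <= threshold``
    left.  ``grid`` is the sorted unique event times of the training data,
    shared by every leaf CHF.
    """

    nodes: list = field(default_factory=list)
    grid: np.ndarray = field(default_factory=lambda: np.empty(0))
    min_node_size: int = 6
    n_features: int = 0


def grow_tree(dataset: SurvivalDataset, min_node_size: int = 6, rng=None) -> SurvivalTree:
    """Grow a survival CART tree by greedy log-rank partitioning.

    Recursion stops when a node has fewer than ``2 * min_node_size``
    subjects, no events, or no admissible split; each leaf stores the
    Nelson-Aalen CHF of its subjects on the tree grid.  ``rng`` is accepted
    for interface symmetry; the exhaustive search is deterministic.
    """
    grid = np.unique(dataset.times[dataset.events == 1])
    tree = SurvivalTree(
        nodes=[], grid=grid, min_node_size=min_node_size, n_features=dataset.p
    )

    def build(subjects) -> int:
        node = _Node(n_samples=subjects.size)
        idx = len(tree.nodes)
        tree.nodes.append(node)
        split = None
        if (
            subjects.size >= 2 * min_node_size
            and dataset.events[subjects].sum() > 0
        ):
            split = find_best_split(dataset, subjects, min_node_size)
        if split is None:
            node.chf = nelson_aalen_chf(
                dataset.times[subjects], dataset.events[subjects], grid
            )
            return idx
        node.var, node.threshold = split
        go_left = dataset.covariates[subjects, node.var] <= node.threshold
        node.left = build(subjects[go_left])
        node.right = build(subjects[~go_left])
        return idx

    build(np.arange(dataset.n))
    return tree


def _leaf_indices(tree: SurvivalTree, X: np.ndarray) -> np.ndarray:
    """Route every row of X to its leaf node index."""
    out = np.zeros(X.shape[0], dtype=int)
    stack = [(0, np.arange(X.shape[0]))]
    while stack:
        node_idx, rows = stack.pop()
        node = tree.nodes[node_idx]
        if node.is_leaf:
            out[rows] = node_idx
            continue
        mask = X[rows, node.var] <= node.threshold
        stack.append((node.left, rows[mask]))
        stack.append((node.right, rows[~mask]))
    return out


def predict_chf_matrix(tree: SurvivalTree, X) -> np.ndarray:
    """Leaf CHFs for a matrix of subjects, shape (n, len(tree.grid))."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != tree.n_features:
        raise ValueError(
            f"expected {tree.n_features} features, got {X.shape[1]}"
        )
    leaves = _leaf_indices(tree, X)
    return np.vstack([tree.nodes[i].chf for i in leaves])


def predict_tree_chf(tree: SurvivalTree, x) -> np.ndarray:
    """CHF step function (values on ``tree.grid``) for one covariate vector."""
    x = np.asarray(x, float)
    if x.ndim != 1:
        raise ValueError("predict_tree_chf expects a single covariate vector")
    return predict_chf_matrix(tree, x[None, :])[0]
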