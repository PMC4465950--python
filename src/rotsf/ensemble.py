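"""Rotation survival forest (RotSF) training and prediction.

Each of the L ensemble members is built from an outer bootstrap D' of the
training data: the variables are randomly partitioned into size-M subsets,
PCA loadings are estimated per subset on an inner bootstrap D'' drawn from
D' (double bagging; with single bagging the loadings are estimated on D'
itself), the block loadings are assembled into a rotation matrix, and a
survival CART tree is grown on the rotated outer sample.  Predictions
average the members' Nelson-Aalen leaf cumulative hazard functions on a
pooled event-time grid; the scalar risk score is the sum of the ensemble
CHF over the grid (a mortality-style score: higher means shorter expected
survival).

Member construction is a pure function of (data, member seed): the i-th
member's random substream is spawned from the master seed independently of
L, so serial and concurrent execution — and any member ordering — agree
bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .data import SurvivalDataset
from .rotation import RotationSpec, build_rotation, rotate
from .tree import SurvivalTree, _Node, grow_tree, predict_chf_matrix

__all__ = [
    "RotSFConfig",
    "RotSFModel",
    "fit",
    "predict_ensemble_chf",
    "predict_risk",
    "oob_risk",
    "oob_cindex",
]


@dataclass(frozen=True)
class RotSFConfig:
    """Ensemble hyper-parameters.

    ``L`` trees (default 1000), variable-subset size ``M`` (default 2),
    tree stopping size ``min_node_size``, ``double_bagging`` on for RotSF
    and off for the single-bagging variant RotSFsb, and the master seed.
    """

    L: int = 1000
    M: int = 2
    min_node_size: int = 6
    double_bagging: bool = True
    scale: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.L < 1:
            raise ValueError("ensemble size L must be >= 1")
        if self.M < 1:
            raise ValueError("subset size M must be >= 1")


@dataclass
class _Member:
    rotation: RotationSpec
    tree: SurvivalTree


@dataclass
class RotSFModel:
    """Fitted ensemble: L (rotation, tree) pairs plus bookkeeping.

    ``inbag`` holds the outer-bootstrap draw counts (L, n); a subject is
    out-of-bag (OOB) for member i iff ``inbag[i, subject] == 0``.  ``grid``
    is the pooled sorted unique event times of the training data onto which
    every member's leaf CHF is carried by right-continuous step
    interpolation.
    """

    members: list
    inbag: np.ndarray
    grid: np.ndarray
    config: RotSFConfig
    names: tuple = field(default=())

    @property
    def L(self) -> int:
        return len(self.members)

    @property
    def p(self) -> int:
        return self.members[0].rotation.p

    def oob_mask(self, i: int) -> np.ndarray:
        return self.inbag[i] == 0

    # -- serialization ----------------------------------------------------

    def to_json(self) -> str:
        """Serialize to a JSON container for refit-free prediction."""
        members = []
        for m in self.members:
            rot = m.rotation
            members.append({
                "partition": [b.tolist() for b in rot.partition],
                "remainder": rot.remainder.tolist(),
                "loadings": [l.tolist() for l in rot.loadings],
                "grid": m.tree.grid.tolist(),
                "nodes": [
                    {
                        "n": nd.n_samples,
                        "var": nd.var,
                        "thr": None if nd.is_leaf else nd.threshold,
                        "left": nd.left,
                        "right": nd.right,
                        "chf": None if nd.chf is None else nd.chf.tolist(),
                    }
                    for nd in m.tree.nodes
                ],
            })
        payload = {
            "format": "rotsf-model",
            "version": 1,
            "config": {
                "L": self.config.L,
                "M": self.config.M,
                "min_node_size": self.config.min_node_size,
                "double_bagging": self.config.double_bagging,
                "scale": self.config.scale,
                "seed": self.config.seed,
            },
            "names": list(self.names),
            "grid": self.grid.tolist(),
            "inbag": self.inbag.tolist(),
            "members": members,
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "RotSFModel":
        payload = json.loads(text)
        if payload.get("format") != "rotsf-model":
            raise ValueError("not a rotsf model container")
        config = RotSFConfig(**payload["config"])
        p = len(payload["names"])
        members = []
        for m in payload["members"]:
            partition = tuple(np.asarray(b, int) for b in m["partition"])
            remainder = np.asarray(m["remainder"], int)
            loadings = tuple(np.asarray(l, float) for l in m["loadings"])
            from .rotation import assemble_rotation

            R = assemble_rotation(partition, remainder, loadings, p)
            rot = RotationSpec(partition, remainder, loadings, R)
            tree = SurvivalTree(
                nodes=[
                    _Node(
                        n_samples=nd["n"],
                        var=nd["var"],
                        threshold=np.nan if nd["thr"] is None else nd["thr"],
                        left=nd["left"],
                        right=nd["right"],
                        chf=None if nd["chf"] is None else np.asarray(nd["chf"]),
                    )
                    for nd in m["nodes"]
                ],
                grid=np.asarray(m["grid"], float),
                min_node_size=config.min_node_size,
                n_features=R.shape[1],
            )
            members.append(_Member(rot, tree))
        return cls(
            members=members,
            inbag=np.asarray(payload["inbag"], int),
            grid=np.asarray(payload["grid"], float),
            config=config,
            names=tuple(payload["names"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "RotSFModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


def _fit_member(dataset: SurvivalDataset, config: RotSFConfig, seed_seq):
    """Build one (rotation, tree) member; pure in (data, member seed)."""
    rng = np.random.default_rng(seed_seq)
    n = dataset.n
    draws = rng.integers(0, n, n)  # outer bootstrap D'
    inbag = np.bincount(draws, minlength=n)
    boot = dataset.subset(draws)
    rotation = build_rotation(
        boot.covariates, config.M, rng,
        inner_bootstrap=config.double_bagging, scale=config.scale,
    )
    rotated = SurvivalDataset(
        boot.times, boot.events, rotate(boot.covariates, rotation.rotation_matrix)
    )
    tree = grow_tree(rotated, min_node_size=config.min_node_size)
    return _Member(rotation, tree), inbag


def fit(dataset: SurvivalDataset, config: RotSFConfig) -> RotSFModel:
    """Train a rotation survival forest.

    Raises if M exceeds the covariate dimension; dataset validity (n >= 2,
    at least one event) is enforced by ``SurvivalDataset`` itself.
    """
    if config.M > dataset.p:
        raise ValueError(
            f"subset size M={config.M} exceeds covariate count p={dataset.p}"
        )
    children = np.random.SeedSequence(config.seed).spawn(config.L)
    members = []
    inbag = np.zeros((config.L, dataset.n), dtype=int)
    for i, child in enumerate(children):
        member, counts = _fit_member(dataset, config, child)
        members.append(member)
        inbag[i] = counts
    grid = np.unique(dataset.times[dataset.events == 1])
    return RotSFModel(members, inbag, grid, config, dataset.names)


def _step_interp(values, member_grid, target_grid):
    """Carry a right-continuous step function onto another grid.

    Zero before the member's first event time, last value after its last.
    ``values`` may be (n, len(member_grid)).
    """
    if member_grid.size == 0:
        return np.zeros(values.shape[:-1] + (target_grid.size,))
    idx = np.searchsorted(member_grid, target_grid, side="right")
    padded = np.concatenate(
        [np.zeros(values.shape[:-1] + (1,)), values], axis=-1
    )
    return padded[..., idx]


def _member_chf(member: _Member, X: np.ndarray, grid: np.ndarray) -> np.ndarray:
    Z = rotate(X, member.rotation.rotation_matrix)
    chf = predict_chf_matrix(member.tree, Z)
    return _step_interp(chf, member.tree.grid, grid)


def predict_ensemble_chf(model: RotSFModel, X_new) -> np.ndarray:
    """Ensemble CHF per subject: unweighted mean of member CHFs on model.grid."""
    X = np.atleast_2d(np.asarray(X_new, float))
    if X.shape[1] != model.p:
        raise ValueError(f"expected {model.p} covariates, got {X.shape[1]}")
    total = np.zeros((X.shape[0], model.grid.size))
    for member in model.members:
        total += _member_chf(member, X, model.grid)
    return total / model.L


def predict_risk(model: RotSFModel, X_new) -> np.ndarray:
    """Mortality-style risk: ensemble CHF summed over the pooled grid."""
    return predict_ensemble_chf(model, X_new).sum(axis=1)


def _member_risk(member: _Member, X: np.ndarray, grid: np.ndarray) -> np.ndarray:
    return _member_chf(member, X, grid).sum(axis=1)


def oob_risk(model: RotSFModel, dataset: SurvivalDataset) -> np.ndarray:
    """Out-of-bag risk per training subject.

    Averages each subject's risk over only the members whose outer
    bootstrap excluded it; NaN flags subjects that were in-bag everywhere
    (possible for small L).
    """
    n = dataset.n
    total = np.zeros(n)
    counts = np.zeros(n)
    for i, member in enumerate(model.members):
        mask = model.oob_mask(i)
        if not mask.any():
            continue
        total[mask] += _member_risk(member, dataset.covariates[mask], model.grid)
        counts[mask] += 1
    with np.errstate(invalid="ignore"):
        out = np.where(counts > 0, total / np.maximum(counts, 1), np.nan)
    return out


def oob_cindex(model: RotSFModel, dataset: SurvivalDataset) -> float:
    """Harrell's C-index of the OOB risk predictions (covered subjects only)."""
    from .evaluation import harrell_c_index

    risk = oob_risk(model, dataset)
    ok = np.isfinite(risk)
    return harrell_c_index(dataset.times[ok], dataset.events[ok], risk[ok])
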