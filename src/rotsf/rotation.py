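"""Per-tree rotation construction.

Each ensemble member re-expresses the covariates before tree training:
the p variables are randomly partitioned into k = floor(p / M) disjoint
subsets of size M, PCA loadings are estimated per subset, and the block
loadings are assembled into a rearranged rotation matrix ``R`` of shape
(p, k * M).  The p mod M remainder variables (RV) left out of every subset
get all-zero rows, so they contribute nothing to that member's features;
a fresh random remainder per member means every variable participates in
the ensemble with overwhelming probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "RotationSpec",
    "partition_variables",
    "block_pca_loadings",
    "assemble_rotation",
    "rotate",
    "rotated_names",
]


@dataclass(frozen=True)
class RotationSpec:
    """One member's variable partition and assembled rotation.

    ``partition`` holds k disjoint ordered index arrays of size M,
    ``remainder`` the p mod M left-out indices, ``loadings`` the k (M, M)
    orthonormal PCA loading blocks (columns ordered by decreasing
    explained variance), and ``rotation_matrix`` the assembled (p, k * M)
    matrix with zero rows for the remainder variables.
    """

    partition: tuple
    remainder: np.ndarray
    loadings: tuple
    rotation_matrix: np.ndarray

    @property
    def p(self) -> int:
        return self.rotation_matrix.shape[0]

    @property
    def subset_size(self) -> int:
        return self.partition[0].size if self.partition else 0


def partition_variables(p: int, M: int, rng) -> tuple:
    """Random partition of {0..p-1} into k = floor(p/M) size-M subsets.

    A uniformly random permutation is chopped into k consecutive blocks;
    the trailing ``p mod M`` indices form the remainder set.
    """
    if not 1 <= M <= p:
        raise ValueError(f"subset size M={M} must satisfy 1 <= M <= p={p}")
    perm = rng.permutation(p)
    k = p // M
    partition = tuple(perm[j * M:(j + 1) * M] for j in range(k))
    remainder = perm[k * M:]
    return partition, remainder


def block_pca_loadings(X_block: np.ndarray, scale: bool = False) -> np.ndarray:
    """Full PCA loading matrix of one variable block.

    Columns are the M principal-axis loading vectors of the column-centered
    (optionally variance-scaled) block, ordered by decreasing explained
    variance, all M retained.  Sign is fixed by making the
    largest-magnitude entry of each column positive.  Rank-deficient
    blocks (constant columns, duplicated rows — common in bootstraps of
    small data) are completed to an orthonormal basis rather than failing.
    """
    X = np.atleast_2d(np.asarray(X_block, float))
    if X.shape[0] < 2:
        raise ValueError("PCA block needs at least two rows")
    Xc = X - X.mean(axis=0)
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        Xc = Xc / np.where(sd > 0, sd, 1.0)
    # full_matrices=False still yields an orthonormal basis of R^M in Vt
    # whenever n-1 >= M; degenerate directions come out with ~zero singular
    # values, already orthonormal to the informative axes.
    if Xc.shape[0] - 1 >= Xc.shape[1]:
        _, _, Vt = np.linalg.svd(Xc, full_matrices=False)
    else:
        _, _, Vt = np.linalg.svd(Xc, full_matrices=True)
    load = Vt.T
    sign = np.sign(load[np.abs(load).argmax(axis=0), np.arange(load.shape[1])])
    return load * np.where(sign == 0, 1.0, sign)


def assemble_rotation(partition, remainder, loadings, p: int) -> np.ndarray:
    """Assemble per-block loadings into the (p, k * M) rotation matrix.

    Row v of the result, for v in subset j, carries v's row of that
    subset's loading block placed in column block j; remainder rows are
    identically zero.  Column blocks follow subset order.
    """
    partition = [np.asarray(b, int) for b in partition]
    remainder = np.asarray(remainder, int)
    all_idx = np.concatenate(partition + [remainder]) if partition else remainder
    if np.unique(all_idx).size != all_idx.size:
        raise ValueError("partition blocks and remainder overlap")
    if all_idx.size != p or (all_idx >= p).any() or (all_idx < 0).any():
        raise ValueError("partition plus remainder must cover {0..p-1} exactly")
    if len(loadings) != len(partition):
        raise ValueError("need one loading block per subset")
    M = partition[0].size if partition else 0
    R = np.zeros((p, len(partition) * M))
    for j, (block, load) in enumerate(zip(partition, loadings)):
        if load.shape != (block.size, block.size):
            raise ValueError("loading block shape inconsistent with subset size")
        R[np.asarray(block), j * M:(j + 1) * M] = load
    return R


def rotate(X: np.ndarray, rotation_matrix: np.ndarray) -> np.ndarray:
    """Project covariates through the rotation: ``X @ R``."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != rotation_matrix.shape[0]:
        raise ValueError(
            f"X has {X.shape[1]} columns, rotation expects {rotation_matrix.shape[0]}"
        )
    return X @ rotation_matrix


def rotated_names(spec: RotationSpec) -> list:
    """Traceability labels '(subset j, component c)' for rotated columns."""
    M = spec.subset_size
    return [f"s{j + 1}c{c + 1}" for j in range(len(spec.partition)) for c in range(M)]


def build_rotation(X: np.ndarray, M: int, rng, inner_bootstrap: bool = True,
                   scale: bool = False) -> RotationSpec:
    """Draw a partition and fit the per-block PCA loadings on ``X``.

    With ``inner_bootstrap`` each block's loadings are estimated on a fresh
    bootstrap of the rows of ``X`` (the double-bagging inner resample);
    otherwise on ``X`` itself.
    """
    n, p = X.shape
    partition, remainder = partition_variables(p, M, rng)
    loadings = []
    for block in partition:
        if inner_bootstrap:
            rows = rng.integers(0, n, n)
            Xb = X[rows][:, block]
        else:
            Xb = X[:, block]
        loadings.append(block_pca_loadings(Xb, scale=scale))
    R = assemble_rotation(partition, remainder, loadings, p)
    return RotationSpec(tuple(partition), remainder, tuple(loadings), R)
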