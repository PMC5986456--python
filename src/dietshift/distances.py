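"""Community dissimilarities: root-JSD, Bray-Curtis, generalized UniFrac.

All metrics return values in [0, 1] on relative-abundance input.  The
generalized UniFrac implementation pre-compiles the tree into a
branch-by-leaf incidence structure (:class:`BranchProfile`) so that per-pair
distances reduce to dense vector arithmetic; this is reused heavily by the
synthetic cohort calibration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import rel_entr
from skbio import TreeNode

from .data_model import AbundanceTable, TableValidationError


@dataclass
class DistanceMatrix:
    """Symmetric nonnegative dissimilarity matrix over sample ids."""

    ids: list[str]
    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if self.data.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate ids")
        if np.any(np.abs(self.data - self.data.T) > 1e-12):
            raise ValueError("matrix not symmetric within 1e-12")
        if np.any(np.diag(self.data) != 0):
            raise ValueError("nonzero diagonal")
        if np.any(self.data < 0):
            raise ValueError("negative dissimilarity")

    @property
    def n(self) -> int:
        return len(self.ids)

    def between(self, a: str, b: str) -> float:
        return float(self.data[self.ids.index(a), self.ids.index(b)])

    def subset(self, ids: list[str]) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(list(ids), self.data[np.ix_(idx, idx)])

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.data, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", float_format="%.12g"
        )

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls([str(i) for i in df.index], df.to_numpy(dtype=float))


def _check_rel_vector(p: np.ndarray, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any(p < 0):
        raise ValueError(f"{name} has negative entries")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"{name} does not sum to 1")
    return p


def jsd_distance(p, q, base: float = 2.0) -> float:
    """Square root of the Jensen-Shannon divergence between p and q.

    With the default log base 2 the result lies in [0, 1].  Zero entries
    contribute zero by the 0*log(0) = 0 convention.
    """
    p = _check_rel_vector(p, "p")
    q = _check_rel_vector(q, "q")
    if p.shape != q.shape:
        raise ValueError("length mismatch")
    m = 0.5 * (p + q)
    div = 0.5 * (rel_entr(p, m).sum() + rel_entr(q, m).sum()) / np.log(base)
    return float(np.sqrt(max(div, 0.0)))


def bray_curtis(x, y) -> float:
    """1 - 2*sum(min(x_i, y_i)) / (sum x + sum y)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("negative entries")
    total = x.sum() + y.sum()
    if total == 0:
        raise ValueError("both vectors are all-zero")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / total)


class BranchProfile:
    """Tree compiled to branch lengths plus a branch-by-leaf incidence matrix.

    Branch i covers the set of leaves under it; ``branch_abundances`` maps a
    samples-by-taxa relative matrix to samples-by-branch totals with one
    matrix product.
    """

    def __init__(self, tree: TreeNode, taxon_ids: list[str]):
        leaf_index = {t: i for i, t in enumerate(taxon_ids)}
        tree_leaves = {t.name for t in tree.tips()}
        unmapped = sorted(set(taxon_ids) - tree_leaves)
        if unmapped:
            raise TableValidationError(
                f"taxa without a tree leaf: {unmapped}"
            )
        lengths = []
        rows = []
        # post-order: leaf sets of internal nodes are unions of child sets
        leafsets: dict[int, np.ndarray] = {}
        for node in tree.postorder(include_self=True):
            if node.is_tip():
                mask = np.zeros(len(taxon_ids), dtype=bool)
                if node.name in leaf_index:
                    mask[leaf_index[node.name]] = True
                leafsets[id(node)] = mask
            else:
                mask = np.zeros(len(taxon_ids), dtype=bool)
                for child in node.children:
                    mask |= leafsets[id(child)]
                leafsets[id(node)] = mask
            if node.is_root():
                continue
            if node.length is None:
                raise TableValidationError("tree has a branch without length")
            if node.length > 0 and mask.any():
                lengths.append(node.length)
                rows.append(mask)
        self.lengths = np.asarray(lengths, dtype=float)
        self.incidence = np.asarray(rows, dtype=float)  # branches x taxa

    def branch_abundances(self, values: np.ndarray) -> np.ndarray:
        """Samples-by-branches matrix of subtree abundance totals."""
        return np.asarray(values) @ self.incidence.T

    def pair_distance(self, ba: np.ndarray, bb: np.ndarray,
                      alpha: float = 0.5) -> float:
        """Generalized UniFrac between two branch-abundance vectors."""
        s = ba + bb
        nz = s > 0
        if not nz.any():
            return 0.0
        w = self.lengths[nz] * s[nz] ** alpha
        num = (w * np.abs(ba[nz] - bb[nz]) / s[nz]).sum()
        den = w.sum()
        return float(num / den) if den > 0 else 0.0

    def rows_vs_matrix(self, ba: np.ndarray, bmat: np.ndarray,
                       alpha: float = 0.5) -> np.ndarray:
        """Distances from one branch-abundance vector to many (vectorized)."""
        s = ba[None, :] + bmat
        with np.errstate(divide="ignore", invalid="ignore"):
            w = self.lengths[None, :] * np.where(s > 0, s, 1.0) ** alpha
            ratio = np.where(s > 0, np.abs(ba[None, :] - bmat) / np.where(s > 0, s, 1.0), 0.0)
            num = (np.where(s > 0, w, 0.0) * ratio).sum(axis=1)
            den = np.where(s > 0, w, 0.0).sum(axis=1)
        return np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)


def generalized_unifrac(
    table: AbundanceTable, tree: TreeNode, alpha: float = 0.5
) -> DistanceMatrix:
    """Full pairwise generalized UniFrac matrix for a relative table."""
    if table.mode != "relative":
        raise TableValidationError("generalized_unifrac expects relative mode")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    profile = BranchProfile(tree, table.taxon_ids)
    bmat = profile.branch_abundances(table.values)
    n = table.n_samples
    d = np.zeros((n, n))
    for i in range(n - 1):
        d[i, i + 1:] = profile.rows_vs_matrix(bmat[i], bmat[i + 1:], alpha)
    d = d + d.T
    return DistanceMatrix(list(table.sample_ids), d)


def _pairwise_jsd(values: np.ndarray, base: float) -> np.ndarray:
    n = values.shape[0]
    logb = np.log(base)
    d = np.zeros((n, n))
    for i in range(n - 1):
        p = values[i][None, :]
        q = values[i + 1:]
        m = 0.5 * (p + q)
        div = 0.5 * (rel_entr(np.broadcast_to(p, q.shape), m).sum(axis=1)
                     + rel_entr(q, m).sum(axis=1)) / logb
        d[i, i + 1:] = np.sqrt(np.maximum(div, 0.0))
    return d + d.T


def _pairwise_bray_curtis(values: np.ndarray) -> np.ndarray:
    n = values.shape[0]
    sums = values.sum(axis=1)
    d = np.zeros((n, n))
    for i in range(n - 1):
        mins = np.minimum(values[i][None, :], values[i + 1:]).sum(axis=1)
        d[i, i + 1:] = 1.0 - 2.0 * mins / (sums[i] + sums[i + 1:])
    return d + d.T


METRICS = ("jsd", "bray_curtis", "gunifrac")


def pairwise_matrix(
    table: AbundanceTable,
    metric: str,
    tree: TreeNode | None = None,
    alpha: float = 0.5,
    jsd_base: float = 2.0,
) -> DistanceMatrix:
    """Full symmetric distance matrix under the named metric."""
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    if metric == "gunifrac":
        if tree is None:
            raise ValueError("gunifrac requires a tree")
        return generalized_unifrac(table, tree, alpha)
    if table.mode != "relative":
        raise TableValidationError("pairwise_matrix expects relative mode")
    if metric == "jsd":
        d = _pairwise_jsd(table.values, jsd_base)
    else:
        d = _pairwise_bray_curtis(table.values)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(table.sample_ids), d)
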