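"""Enterotyping and its bootstrap stability refinement (permatyping).

Enterotypes: genus-level root-JSD matrix, deterministic PAM (BUILD + SWAP),
cluster count chosen by the Calinski-Harabasz index on a principal-coordinate
embedding.  Permatyping re-fits the clustering on bootstrap resamples, maps
replicate clusters back to the base solution by maximal sample overlap, and
discards samples whose assignment is unstable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import fisher_exact
from sklearn.metrics import calinski_harabasz_score, silhouette_samples

from .data_model import AbundanceTable, PairedDesign
from .distances import DistanceMatrix, pairwise_matrix


@dataclass
class TypingResult:
    k: int
    labels: np.ndarray          # 1..k, aligned with sample_ids
    medoids: list[str]          # medoid sample id per cluster (1..k order)
    sample_ids: list[str]
    cost: float                 # total within-cluster distance to medoid
    quality: dict[int, float] = field(default_factory=dict)  # per-k CH score

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.min() < 1 or self.labels.max() > self.k:
            raise ValueError("labels out of range 1..k")
        for c in range(1, self.k + 1):
            members = [self.sample_ids[i] for i in np.flatnonzero(self.labels == c)]
            if not members:
                raise ValueError(f"cluster {c} is empty")
            if self.medoids[c - 1] not in members:
                raise ValueError(f"medoid of cluster {c} not in cluster")

    def cluster_sizes(self) -> dict[int, int]:
        return {c: int((self.labels == c).sum()) for c in range(1, self.k + 1)}


@dataclass
class PermatypeResult:
    base: TypingResult
    stability: np.ndarray        # per sample, aligned with base.sample_ids
    core_labels: dict[str, int]  # stable samples only, base cluster labels
    unclassified: list[str]
    n_bootstrap: int
    threshold: float
    seed: int
    n_skipped: int = 0


# ---------------------------------------------------------------------------
# PAM

def _assignment_cost(d: np.ndarray, medoids: np.ndarray):
    sub = d[:, medoids]
    nearest = np.argmin(sub, axis=1)
    # a medoid always belongs to its own cluster, even when duplicate
    # points make the argmin tie with another medoid
    nearest[medoids] = np.arange(len(medoids))
    cost = sub[np.arange(d.shape[0]), nearest].sum()
    return nearest, cost


def _pam_build(d: np.ndarray, k: int) -> np.ndarray:
    n = d.shape[0]
    medoids = [int(np.argmin(d.sum(axis=0)))]
    for _ in range(1, k):
        current = d[:, medoids].min(axis=1)
        # gain of adding candidate j: sum of reductions over all points
        gains = np.maximum(current[:, None] - d, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    return np.asarray(sorted(medoids))


def _pam_exact(d: np.ndarray, k: int) -> np.ndarray:
    """Exact minimum-cost medoid set by lexicographic enumeration.

    Used for small instances where the search space is trivial; guarantees
    the global optimum of the k-medoids objective and breaks cost ties in
    favour of the lowest sample indices.
    """
    import itertools

    best_cost = np.inf
    best = None
    for medoids in itertools.combinations(range(d.shape[0]), k):
        cost = d[:, medoids].min(axis=1).sum()
        if cost < best_cost - 1e-12:
            best_cost = cost
            best = medoids
    return np.asarray(best)


_EXACT_SEARCH_LIMIT = 2000  # max medoid subsets to enumerate exactly


def pam(dist: DistanceMatrix, k: int) -> TypingResult:
    """Deterministic partitioning around medoids.

    Small instances (at most ``_EXACT_SEARCH_LIMIT`` candidate medoid sets)
    are solved exactly by enumeration; larger ones use greedy BUILD followed
    by a steepest-descent SWAP phase.  Ties are broken by lowest sample
    index, so the result is a pure function of the distance matrix.
    Cluster indices are assigned in ascending medoid order.
    """
    import math

    d = dist.data
    n = d.shape[0]
    if not 2 <= k <= n - 1:
        if k == n:
            # degenerate but well-defined: every sample its own medoid
            labels = np.arange(1, n + 1)
            return TypingResult(k, labels, list(dist.ids), list(dist.ids), 0.0)
        raise ValueError(f"k={k} outside 2..{n - 1}")

    if math.comb(n, k) <= _EXACT_SEARCH_LIMIT:
        medoids = _pam_exact(d, k)
        nearest, cost = _assignment_cost(d, medoids)
        labels = nearest + 1
        return TypingResult(
            k, labels, [dist.ids[m] for m in medoids], list(dist.ids),
            float(cost),
        )

    medoids = _pam_build(d, k)
    _, cost = _assignment_cost(d, medoids)
    while True:
        best = (0.0, None, None)
        non_medoids = np.setdiff1d(np.arange(n), medoids)
        for mi, m in enumerate(medoids):
            others = np.delete(medoids, mi)
            d_rest = d[:, others].min(axis=1)
            # cost after swapping m -> h, for every candidate h at once
            new_costs = np.minimum(d_rest[:, None], d[:, non_medoids]).sum(axis=0)
            j = int(np.argmin(new_costs))
            delta = new_costs[j] - cost
            if delta < best[0] - 1e-12:
                best = (delta, mi, non_medoids[j])
        if best[1] is None:
            break
        medoids[best[1]] = best[2]
        medoids = np.sort(medoids)
        _, cost = _assignment_cost(d, medoids)

    nearest, cost = _assignment_cost(d, medoids)
    labels = nearest + 1
    return TypingResult(
        k, labels, [dist.ids[m] for m in medoids], list(dist.ids), float(cost)
    )


# ---------------------------------------------------------------------------
# cluster quality

def pcoa_embedding(dist: DistanceMatrix, tol: float = 1e-10) -> np.ndarray:
    """Classical MDS coordinates keeping all positive-eigenvalue axes."""
    d2 = dist.data ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > tol * max(evals.max(), 1.0)
    return evecs[:, keep] * np.sqrt(evals[keep])


def _check_labels(labels: np.ndarray, n: int):
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (n,):
        raise ValueError("labels length mismatch")
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    if len(uniq) >= n:
        raise ValueError("as many clusters as samples")
    return labels


def calinski_harabasz(dist: DistanceMatrix, labels) -> float:
    """Calinski-Harabasz index computed on the PCoA embedding of `dist`."""
    labels = _check_labels(labels, dist.n)
    coords = pcoa_embedding(dist)
    return float(calinski_harabasz_score(coords, labels))


def mean_silhouette(dist: DistanceMatrix, labels) -> float:
    """Mean silhouette width; members of singleton clusters contribute 0."""
    labels = _check_labels(labels, dist.n)
    s = silhouette_samples(dist.data, labels, metric="precomputed")
    return float(s.mean())


# ---------------------------------------------------------------------------
# enterotyping

def enterotype(
    table: AbundanceTable,
    k_range: range = range(2, 11),
    jsd_base: float = 2.0,
    dist: DistanceMatrix | None = None,
) -> TypingResult:
    """JSD + PAM clustering; k selected by maximal Calinski-Harabasz.

    Ties go to the smaller k.  `dist` may be supplied to skip the JSD
    computation (e.g. inside the bootstrap).
    """
    if dist is None:
        dist = pairwise_matrix(table, "jsd", jsd_base=jsd_base)
    n = dist.n
    ks = [k for k in k_range if 2 <= k <= n - 1]
    if len(ks) < len(list(k_range)):
        warnings.warn(f"k_range truncated to {ks} for n={n}")
    if not ks:
        raise ValueError(f"no admissible k for n={n}")
    results = {}
    quality = {}
    for k in ks:
        res = pam(dist, k)
        results[k] = res
        quality[k] = calinski_harabasz(dist, res.labels)
    best_k = max(ks, key=lambda k: (quality[k], -k))
    best = results[best_k]
    best.quality = quality
    return best


def _match_clusters(base_labels: np.ndarray, rep_labels: np.ndarray,
                    k: int) -> dict[int, int] | None:
    """Greedy maximal-overlap mapping from replicate clusters to base clusters.

    Overlaps are counted over the samples shared by both label vectors
    (NaN-free positions).  Ties broken by larger replicate cluster size,
    then by lower cluster index.  Returns None if some replicate cluster
    cannot be matched.
    """
    contingency = np.zeros((k, k), dtype=int)
    for rc in range(1, k + 1):
        for bc in range(1, k + 1):
            contingency[rc - 1, bc - 1] = int(
                ((rep_labels == rc) & (base_labels == bc)).sum()
            )
    rep_sizes = [(rep_labels == rc).sum() for rc in range(1, k + 1)]
    mapping: dict[int, int] = {}
    used: set[int] = set()
    cells = [
        (contingency[rc, bc], rep_sizes[rc], -rc, -bc, rc, bc)
        for rc in range(k) for bc in range(k)
    ]
    for overlap, _, _, _, rc, bc in sorted(cells, reverse=True):
        if (rc + 1) in mapping or bc in used:
            continue
        mapping[rc + 1] = bc + 1
        used.add(bc)
    if len(mapping) < k:
        return None
    return mapping


def permatype(
    table: AbundanceTable,
    n_bootstrap: int = 100,
    threshold: float = 0.8,
    seed: int = 0,
    k_range: range = range(2, 11),
    jsd_base: float = 2.0,
    max_skip_frac: float = 0.2,
) -> PermatypeResult:
    """Bootstrap shrinkage of enterotypes.

    The base enterotype is fit on all samples; each bootstrap replicate
    resamples samples with replacement, re-clusters at the base k, and maps
    replicate clusters to base clusters by maximal overlap.  A sample's
    stability is the fraction of replicates containing it in which its mapped
    label agrees with its base label; samples below `threshold` are
    unclassified.  Resampling is indexed by sorted sample id, so the result
    does not depend on sample order.
    """
    if n_bootstrap < 10:
        raise ValueError("n_bootstrap must be >= 10")
    dist = pairwise_matrix(table, "jsd", jsd_base=jsd_base)
    base = enterotype(table, k_range=k_range, dist=dist)
    k = base.k
    n = dist.n

    order = np.argsort(np.asarray(dist.ids, dtype=object))
    rng = np.random.default_rng(seed)
    appearances = np.zeros(n)
    agreements = np.zeros(n)
    n_skipped = 0
    for _ in range(n_bootstrap):
        draw = order[rng.integers(0, n, size=n)]
        uniq, first_pos = np.unique(draw, return_index=True)
        if len(uniq) <= k:
            n_skipped += 1
            continue
        sub = DistanceMatrix(
            [dist.ids[i] for i in uniq], dist.data[np.ix_(uniq, uniq)]
        )
        try:
            rep = pam(sub, k)
        except ValueError:
            n_skipped += 1
            continue
        if len(np.unique(rep.labels)) < k:
            n_skipped += 1
            continue
        mapping = _match_clusters(base.labels[uniq], rep.labels, k)
        if mapping is None:
            n_skipped += 1
            continue
        mapped = np.array([mapping[l] for l in rep.labels])
        appearances[uniq] += 1
        agreements[uniq] += mapped == base.labels[uniq]
    if n_skipped > max_skip_frac * n_bootstrap:
        raise RuntimeError(
            f"{n_skipped}/{n_bootstrap} bootstrap replicates unusable"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        stability = np.where(appearances > 0, agreements / np.maximum(appearances, 1), 0.0)
    stable = stability >= threshold
    core_labels = {
        dist.ids[i]: int(base.labels[i]) for i in np.flatnonzero(stable)
    }
    unclassified = [dist.ids[i] for i in np.flatnonzero(~stable)]
    return PermatypeResult(
        base=base, stability=stability, core_labels=core_labels,
        unclassified=unclassified, n_bootstrap=n_bootstrap,
        threshold=threshold, seed=seed, n_skipped=n_skipped,
    )


# ---------------------------------------------------------------------------
# cluster descriptors

def driver_taxa(
    typing: TypingResult, table: AbundanceTable, top_m: int = 5
) -> dict[int, list[tuple[str, float]]]:
    """Per cluster, taxa ranked by mean abundance in cluster minus mean outside."""
    if typing.sample_ids != list(table.sample_ids):
        table = table.select_samples(typing.sample_ids)
    out: dict[int, list[tuple[str, float]]] = {}
    for c in range(1, typing.k + 1):
        inside = typing.labels == c
        if not inside.any() or inside.all():
            raise ValueError(f"cluster {c} empty or all-encompassing")
        score = table.values[inside].mean(axis=0) - table.values[~inside].mean(axis=0)
        order = np.argsort(-score)[: min(top_m, table.n_taxa)]
        out[c] = [(table.taxon_ids[j], float(score[j])) for j in order]
    return out


def transition_analysis(
    before_labels: dict[str, int],
    after_labels: dict[str, int],
    design: PairedDesign,
    focus_cluster: int,
) -> dict:
    """Permatype transition matrix plus Fisher's exact test for `focus_cluster`.

    Builds the 2x2 table (baseline in focus cluster vs not) x (stayed in its
    baseline cluster vs moved) over subjects with labels at both time points,
    and a full k-by-k transition matrix.
    """
    pairs = []
    n_dropped = 0
    for rec in design.records:
        b = before_labels.get(rec.sample_before)
        a = after_labels.get(rec.sample_after)
        if b is None or a is None:
            n_dropped += 1
            continue
        pairs.append((b, a))
    if not pairs:
        raise ValueError("no subjects with labels at both time points")
    ks = sorted({b for b, _ in pairs} | {a for _, a in pairs})
    kmax = max(ks)
    transition = np.zeros((kmax, kmax), dtype=int)
    for b, a in pairs:
        transition[b - 1, a - 1] += 1
    in_focus = np.array([b == focus_cluster for b, _ in pairs])
    if not in_focus.any():
        raise ValueError(f"focus cluster {focus_cluster} empty at baseline")
    stayed = np.array([b == a for b, a in pairs])
    contingency = np.array([
        [int((in_focus & stayed).sum()), int((in_focus & ~stayed).sum())],
        [int((~in_focus & stayed).sum()), int((~in_focus & ~stayed).sum())],
    ])
    _, p = fisher_exact(contingency, alternative="two-sided")
    return {
        "contingency": contingency,
        "fisher_p": float(p),
        "transition_matrix": transition,
        "n_subjects": len(pairs),
        "n_dropped": n_dropped,
    }
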