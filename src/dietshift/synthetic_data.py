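"""Synthetic paired cohorts with planted, recoverable structure.

The generator plants: (1) community types with distinct genus-level Dirichlet
centroids, (2) a bimodal paired-shift magnitude (responder / non-responder
subpopulations whose paired generalized-UniFrac dissimilarities are
calibrated per subject by bisection), (3) a higher baseline
Bacteroidetes:Firmicutes ratio in responders (the per-sample ratio is set
exactly to a Gamma draw with the group's mean), and (4) an overall
intervention direction (Bacteroidetes down, Firmicutes/Actinobacteria up).
Everything is deterministic given the config seed, and every planted truth
is recorded for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from skbio import TreeNode

from .data_model import (
    AbundanceTable,
    Lineage,
    PairRecord,
    PairedDesign,
    RANKS,
)
from .distances import BranchProfile

LINEAGE_SEP = "|"


@dataclass
class CohortConfig:
    n_subjects: int = 215
    n_taxa: int = 60
    n_types: int = 3
    concentration: float = 150.0
    responder_fraction: float = 85 / 215
    shift_means: tuple = (0.19, 0.30)   # (non_responder, responder)
    shift_sds: tuple = (0.03, 0.05)
    bf_ratio_means: tuple = (0.06, 0.22)  # (non_responder, responder)
    bf_ratio_cv: float = 0.6
    mixture_fraction: float = 0.0
    sequencing_depth: int = 20000
    unifrac_alpha: float = 0.5
    type_boost: float = 8.0
    n_signature: int = 6
    direction_jitter: float = 0.3
    calibration_tol: float = 0.005
    effect_R2: float | None = None      # advisory; realized value is recorded
    tree_seed: int | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValueError("responder_fraction outside [0, 1]")
        if not 0.0 <= self.mixture_fraction <= 1.0:
            raise ValueError("mixture_fraction outside [0, 1]")
        if list(self.shift_means) != sorted(self.shift_means):
            raise ValueError("shift_means must be ordered ascending")
        if self.n_types < 1 or self.n_taxa < 8:
            raise ValueError("need n_types >= 1 and n_taxa >= 8")


@dataclass
class PlantedTruth:
    subject_ids: list[str]
    type_labels: list[int]            # 1..n_types, 0 for mixture subjects
    responder: list[bool]
    mixture: list[bool]
    target_dissim: list[float]
    realized_dissim: list[float]      # on latent relative profiles
    realized_dissim_counts: list[float]  # on count-derived profiles
    shift_direction: list[float]      # base direction, one weight per taxon
    realized_R2: float | None
    realized_omega2: float | None
    config: dict

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, default=float)


@dataclass
class Cohort:
    table_before: AbundanceTable
    table_after: AbundanceTable
    design: PairedDesign
    tree: TreeNode
    truth: PlantedTruth


def random_tree(n_leaves: int, seed: int = 0, names=None) -> TreeNode:
    """Random coalescent-style topology with exponential branch lengths."""
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    rng = np.random.default_rng(seed)
    if names is None:
        names = [f"t{i:04d}" for i in range(n_leaves)]
    if len(names) != n_leaves:
        raise ValueError("names length mismatch")
    nodes = [TreeNode(name=str(n)) for n in names]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        a.length = float(rng.exponential(0.5))
        b.length = float(rng.exponential(0.5))
        nodes.append(TreeNode(children=[a, b]))
    return nodes[0]


def _make_taxonomy(n_taxa: int, rng: np.random.Generator):
    """Genus ids, lineages, and per-phylum column masks."""
    n_bact = max(3, int(round(0.25 * n_taxa)))
    n_act = max(2, int(round(0.12 * n_taxa)))
    n_other = max(2, int(round(0.08 * n_taxa)))
    n_firm = n_taxa - n_bact - n_act - n_other
    phyla = (
        ["Bacteroidetes"] * n_bact
        + ["Firmicutes"] * n_firm
        + ["Actinobacteria"] * n_act
        + ["Proteobacteria"] * n_other
    )
    classes = {
        "Bacteroidetes": ("Bacteroidia", "Bacteroidales"),
        "Firmicutes": ("Clostridia", "Clostridiales"),
        "Actinobacteria": ("Actinobacteria_c", "Bifidobacteriales"),
        "Proteobacteria": ("Gammaproteobacteria", "Enterobacteriales"),
    }
    taxon_ids, lineages = [], {}
    fam_counter: dict[str, int] = {}
    for i, phylum in enumerate(phyla):
        cls, order = classes[phylum]
        fam_idx = fam_counter.setdefault(phylum, 0)
        family = f"{phylum[:4]}fam{1 + i // 4:02d}"
        fam_counter[phylum] += 1
        genus = f"g{i:03d}"
        lin = Lineage((
            "Bacteria", phylum, cls, order, family, genus, "",
        ))
        tid = lin.format(sep=LINEAGE_SEP)
        taxon_ids.append(tid)
        lineages[tid] = lin
    masks = {
        p: np.array([ph == p for ph in phyla]) for p in set(phyla)
    }
    return taxon_ids, lineages, masks


def _type_centroids(config: CohortConfig, masks, rng) -> np.ndarray:
    """Strictly positive genus centroids, one per type, distinct signatures."""
    n = config.n_taxa
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n)
    base /= base.sum()
    firm_cols = np.flatnonzero(masks["Firmicutes"])
    rng.shuffle(firm_cols)
    n_sig = min(config.n_signature, len(firm_cols) // config.n_types)
    if n_sig < 1:
        raise ValueError("not enough Firmicutes genera for type signatures")
    centroids = []
    for t in range(config.n_types):
        c = base.copy()
        sig = firm_cols[t * n_sig:(t + 1) * n_sig]
        c[sig] *= config.type_boost
        centroids.append(c / c.sum())
    return np.asarray(centroids)


def _set_bf_ratio(p: np.ndarray, masks, ratio: float) -> np.ndarray:
    """Rescale the Bacteroidetes block so that B/F equals `ratio` exactly."""
    b = masks["Bacteroidetes"]
    f = masks["Firmicutes"]
    sb, sf = p[b].sum(), p[f].sum()
    if sb == 0 or sf == 0:
        return p
    out = p.copy()
    out[b] *= ratio * sf / sb
    return out / out.sum()


def _perturb(p: np.ndarray, w: np.ndarray, m: float) -> np.ndarray:
    q = p * np.exp(m * w)
    return q / q.sum()


def _calibrate_shift(
    p_branch_fn, p: np.ndarray, w: np.ndarray, target: float,
    tol: float, max_m: float = 50.0,
):
    """Bisection on the perturbation magnitude to hit a target dissimilarity.

    `p_branch_fn(profile_vector)` must return the generalized-UniFrac
    distance between `p` and the perturbed profile.
    """
    def dist_at(m: float) -> float:
        return p_branch_fn(_perturb(p, w, m))

    hi = 1.0
    d_hi = dist_at(hi)
    while d_hi < target and hi < max_m:
        hi *= 2.0
        d_hi = dist_at(hi)
    if d_hi < target:
        raise ValueError(
            f"target dissimilarity {target:.3f} unreachable; attainable "
            f"range is [0, {d_hi:.3f}]"
        )
    lo = 0.0
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        d = dist_at(mid)
        if abs(d - target) <= tol:
            return mid, d
        if d < target:
            lo = mid
        else:
            hi = mid
    mid = 0.5 * (lo + hi)
    return mid, dist_at(mid)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a paired cohort, its tree, pairing manifest and truth record."""
    rng = np.random.default_rng(config.seed)
    taxon_ids, lineages, masks = _make_taxonomy(config.n_taxa, rng)
    tree_seed = (config.tree_seed if config.tree_seed is not None
                 else config.seed + 104729)
    tree = random_tree(config.n_taxa, seed=tree_seed, names=taxon_ids)
    profile = BranchProfile(tree, taxon_ids)
    centroids = _type_centroids(config, masks, rng)

    ns = config.n_subjects
    n_resp = int(round(config.responder_fraction * ns))
    responder = np.zeros(ns, dtype=bool)
    responder[rng.permutation(ns)[:n_resp]] = True
    n_mix = int(round(config.mixture_fraction * ns))
    mixture = np.zeros(ns, dtype=bool)
    mixture[rng.permutation(ns)[:n_mix]] = True
    type_labels = rng.integers(1, config.n_types + 1, size=ns)
    type_labels[mixture] = 0

    # base intervention direction: Bacteroidetes down, Firmicutes and
    # Actinobacteria up
    w_base = np.zeros(config.n_taxa)
    w_base[masks["Bacteroidetes"]] = -1.0
    w_base[masks["Firmicutes"]] = 0.6
    w_base[masks["Actinobacteria"]] = 1.0

    gamma_shape = 1.0 / config.bf_ratio_cv ** 2

    before_rel = np.zeros((ns, config.n_taxa))
    after_rel = np.zeros((ns, config.n_taxa))
    targets = np.zeros(ns)
    realized = np.zeros(ns)
    for s in range(ns):
        if mixture[s]:
            a, b = rng.choice(config.n_types, size=2, replace=False)
            centroid = 0.5 * (centroids[a] + centroids[b])
        else:
            centroid = centroids[type_labels[s] - 1]
        p = rng.dirichlet(config.concentration * centroid)
        p = np.maximum(p, 1e-12)
        p /= p.sum()
        g = int(responder[s])
        ratio = rng.gamma(gamma_shape,
                          config.bf_ratio_means[g] / gamma_shape)
        p = _set_bf_ratio(p, masks, ratio)

        target = rng.normal(config.shift_means[g], config.shift_sds[g])
        target = float(np.clip(target, 0.02, 0.95))
        w = w_base + config.direction_jitter * rng.standard_normal(
            config.n_taxa
        )
        bp = profile.branch_abundances(p[None, :])[0]

        def dist_to(q: np.ndarray) -> float:
            bq = profile.branch_abundances(q[None, :])[0]
            return profile.pair_distance(bp, bq, config.unifrac_alpha)

        m, d = _calibrate_shift(dist_to, p, w, target,
                                config.calibration_tol)
        before_rel[s] = p
        after_rel[s] = _perturb(p, w, m)
        targets[s] = target
        realized[s] = d

    depth = config.sequencing_depth
    before_counts = np.array(
        [rng.multinomial(depth, before_rel[s]) for s in range(ns)],
        dtype=float,
    )
    after_counts = np.array(
        [rng.multinomial(depth, after_rel[s]) for s in range(ns)],
        dtype=float,
    )

    subject_ids = [f"S{s + 1:04d}" for s in range(ns)]
    before_ids = [f"{sid}_B" for sid in subject_ids]
    after_ids = [f"{sid}_A" for sid in subject_ids]
    table_before = AbundanceTable(
        before_ids, list(taxon_ids), before_counts, dict(lineages), "counts"
    )
    table_after = AbundanceTable(
        after_ids, list(taxon_ids), after_counts, dict(lineages), "counts"
    )
    design = PairedDesign([
        PairRecord(sid, b, a)
        for sid, b, a in zip(subject_ids, before_ids, after_ids)
    ])

    # realized dissimilarity on the count-derived profiles, and overall
    # before/after variance decomposition
    rel_b = before_counts / before_counts.sum(axis=1, keepdims=True)
    rel_a = after_counts / after_counts.sum(axis=1, keepdims=True)
    bb = profile.branch_abundances(rel_b)
    ba = profile.branch_abundances(rel_a)
    realized_counts = np.array([
        profile.pair_distance(bb[s], ba[s], config.unifrac_alpha)
        for s in range(ns)
    ])
    realized_r2, realized_w2 = _before_after_variance(
        profile, np.vstack([bb, ba]), ns, config.unifrac_alpha
    )

    truth = PlantedTruth(
        subject_ids=subject_ids,
        type_labels=[int(t) for t in type_labels],
        responder=[bool(r) for r in responder],
        mixture=[bool(m_) for m_ in mixture],
        target_dissim=[float(t) for t in targets],
        realized_dissim=[float(d) for d in realized],
        realized_dissim_counts=[float(d) for d in realized_counts],
        shift_direction=[float(v) for v in w_base],
        realized_R2=realized_r2,
        realized_omega2=realized_w2,
        config={k: (list(v) if isinstance(v, tuple) else v)
                for k, v in asdict(config).items()},
    )
    return Cohort(table_before, table_after, design, tree, truth)


def _before_after_variance(profile: BranchProfile, bmat: np.ndarray,
                           ns: int, alpha: float):
    """R^2 and omega^2 of the before/after split on the full gUniFrac matrix."""
    n = bmat.shape[0]
    d = np.zeros((n, n))
    for i in range(n - 1):
        d[i, i + 1:] = profile.rows_vs_matrix(bmat[i], bmat[i + 1:], alpha)
    d2 = (d + d.T) ** 2
    sst = d2.sum() / (2.0 * n)
    ssw = (d2[:ns, :ns].sum() + d2[ns:, ns:].sum()) / (2.0 * ns)
    ssb = sst - ssw
    msw = ssw / (n - 2)
    return float(ssb / sst), float(max((ssb - msw) / (sst + msw), 0.0))
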