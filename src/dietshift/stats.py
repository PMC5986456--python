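"""Diversity indices, compositional transforms, paired tests, cooperatives."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .data_model import AbundanceTable, PairedDesign, TableValidationError


def shannon(x, base: float = 2.0) -> float:
    """Shannon entropy of a count or relative-abundance vector."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("negative entries")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero input")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum() / np.log(base))


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1*(F1-1)/(2*(F2+1))."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("negative counts")
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("chao1 requires integer counts")
    counts = np.round(counts).astype(int)
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    return float(s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1)))


def rarefy(counts, depth: int, seed: int = 0) -> np.ndarray:
    """Subsample a count vector without replacement to exactly `depth`."""
    counts = np.asarray(counts)
    if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
        raise ValueError("rarefy requires nonnegative integer counts")
    counts = np.round(counts).astype(np.int64)
    if counts.sum() < depth:
        raise ValueError(
            f"depth {depth} exceeds sample total {int(counts.sum())}"
        )
    rng = np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(counts, depth).astype(np.int64)


def rarefy_table(table: AbundanceTable, depth: int, seed: int = 0):
    """Rarefy every sample; samples below `depth` are dropped and reported."""
    if table.mode != "counts":
        raise TableValidationError("rarefy_table requires counts mode")
    kept, dropped, rows = [], [], []
    rng = np.random.default_rng(seed)
    for sid, row in zip(table.sample_ids, table.values):
        if row.sum() < depth:
            dropped.append(sid)
            continue
        sub_seed = int(rng.integers(0, 2**31 - 1))
        rows.append(rarefy(row, depth, seed=sub_seed))
        kept.append(sid)
    if not kept:
        raise TableValidationError("every sample below rarefaction depth")
    out = AbundanceTable(
        kept, list(table.taxon_ids), np.asarray(rows, dtype=float),
        dict(table.lineages), "counts",
    )
    return out, dropped


def clr(vector, pseudocount: float = 0.5) -> np.ndarray:
    """Centered log-ratio transform of a count vector (plus pseudocount)."""
    x = np.asarray(vector, dtype=float)
    if np.any(x < 0):
        raise ValueError("negative entries")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    logs = np.log(x + pseudocount)
    return logs - logs.mean()


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment with monotonicity enforcement."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(n)
    adjusted[order] = np.minimum(ranked, 1.0)
    return adjusted


def _wilcoxon_paired(diffs: np.ndarray, exact_max_n: int = 25) -> float:
    """Two-sided Wilcoxon signed-rank p on a vector of paired differences.

    Zero differences are discarded (standard convention); all-zero -> p = 1.
    Exact null for <= `exact_max_n` nonzero pairs, else normal approximation
    with continuity correction.
    """
    nz = diffs[diffs != 0]
    if len(nz) == 0:
        return 1.0
    method = "exact" if len(nz) <= exact_max_n else "approx"
    res = sps.wilcoxon(nz, alternative="two-sided", correction=True,
                       method=method)
    return float(res.pvalue)


def paired_clr_test(
    table_before: AbundanceTable,
    table_after: AbundanceTable,
    design: PairedDesign,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-taxon Wilcoxon signed-rank test on paired CLR differences + BH.

    Returns a DataFrame indexed by taxon with columns p, adjusted_p and
    median_clr_diff (after minus before).
    """
    if table_before.taxon_ids != table_after.taxon_ids:
        raise TableValidationError("taxon sets differ between time points")
    if len(design.records) < 6:
        raise TableValidationError("need at least 6 subjects")
    before = np.array([
        clr(table_before.sample_vector(r.sample_before), pseudocount)
        for r in design.records
    ])
    after = np.array([
        clr(table_after.sample_vector(r.sample_after), pseudocount)
        for r in design.records
    ])
    diffs = after - before
    pvals = np.array([_wilcoxon_paired(diffs[:, j])
                      for j in range(diffs.shape[1])])
    return pd.DataFrame(
        {
            "p": pvals,
            "adjusted_p": bh_adjust(pvals),
            "median_clr_diff": np.median(diffs, axis=0),
        },
        index=table_before.taxon_ids,
    )


# ---------------------------------------------------------------------------
# cooperatives

@dataclass
class CooperativeSet:
    components: dict[str, list[str]]  # name -> member taxon ids
    edges: list[tuple[str, str]]

    def __post_init__(self):
        seen: set[str] = set()
        for name, members in self.components.items():
            overlap = seen & set(members)
            if overlap:
                raise ValueError(f"taxa in several cooperatives: {overlap}")
            seen |= set(members)


def load_edge_list(path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError("edge list needs source and target columns")
    return list(zip(df[cols[0]], df[cols[1]]))


def cooperatives(
    edge_list,
    min_size: int = 3,
    table: AbundanceTable | None = None,
) -> CooperativeSet:
    """Connected components of the co-occurrence graph with >= min_size taxa.

    If a table is supplied, each cooperative is named after the family of its
    highest-mean-abundance member ("<family>-dominant"); otherwise
    "coop_1", "coop_2", ... in decreasing size order.
    """
    edges = []
    for u, v in edge_list:
        if u == v:
            warnings.warn(f"self-loop on {u!r} dropped")
            continue
        edges.append((u, v))
    g = nx.Graph()
    g.add_edges_from(edges)
    comps = [sorted(c) for c in nx.connected_components(g) if len(c) >= min_size]
    comps.sort(key=lambda c: (-len(c), c[0]))
    named: dict[str, list[str]] = {}
    for i, members in enumerate(comps, start=1):
        name = f"coop_{i}"
        if table is not None:
            present = [m for m in members if m in table.taxon_ids]
            if present:
                means = {
                    m: table.values[:, table.taxon_ids.index(m)].mean()
                    for m in present
                }
                top = max(means, key=lambda m: means[m])
                family = table.lineages[top].name_at("family") or top
                name = f"{family}-dominant"
                if name in named:
                    name = f"{family}-dominant_{i}"
        named[name] = members
    return CooperativeSet(named, edges)


def cooperative_abundance(
    coops: CooperativeSet, table: AbundanceTable
) -> pd.DataFrame:
    """Samples-by-cooperatives matrix of summed member abundances."""
    out = {}
    for name, members in coops.components.items():
        cols = [table.taxon_ids.index(m) for m in members
                if m in table.taxon_ids]
        missing = [m for m in members if m not in table.taxon_ids]
        if not cols:
            raise TableValidationError(
                f"every member of {name!r} missing from table"
            )
        if missing:
            warnings.warn(f"{name}: members absent from table: {missing}")
        out[name] = table.values[:, cols].sum(axis=1)
    return pd.DataFrame(out, index=table.sample_ids)
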