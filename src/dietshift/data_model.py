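"""Abundance tables, taxonomic lineages, trees and pairing manifests.

The central object is :class:`AbundanceTable`, a samples-by-taxa matrix in
either ``counts`` or ``relative`` mode, with one :class:`Lineage` per taxon.
Tables are read from TSV (taxa rows by sample columns, Greengenes-style
lineage strings in the first column) or from BIOM 2.x HDF5 files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

RANK_PREFIXES = {
    "kingdom": "k__",
    "phylum": "p__",
    "class": "c__",
    "order": "o__",
    "family": "f__",
    "genus": "g__",
    "species": "s__",
}


class TableValidationError(ValueError):
    """Raised when a table, lineage, design or tree violates its contract."""


class LineageParseError(TableValidationError):
    pass


@dataclass(frozen=True)
class Lineage:
    """Ordered ranked lineage from kingdom to species.

    ``names[i]`` is the taxon name at ``RANKS[i]``; an empty string marks an
    unclassified level.
    """

    names: tuple[str, ...]

    def __post_init__(self):
        if len(self.names) != len(RANKS):
            raise LineageParseError(
                f"lineage must have {len(RANKS)} ranks, got {len(self.names)}"
            )

    @classmethod
    def parse(cls, text: str, sep: str = ";") -> "Lineage":
        """Parse a prefixed lineage string like ``k__Bacteria;p__Firmicutes``.

        Missing trailing ranks are allowed and flagged unclassified.
        """
        names = [""] * len(RANKS)
        parts = [p.strip() for p in text.split(sep)]
        for i, part in enumerate(parts):
            if part == "":
                continue
            if i >= len(RANKS):
                raise LineageParseError(f"too many ranks in lineage {text!r}")
            prefix = RANK_PREFIXES[RANKS[i]]
            if not part.startswith(prefix):
                raise LineageParseError(
                    f"rank {i} of lineage {text!r} lacks prefix {prefix!r}"
                )
            names[i] = part[len(prefix):]
        return cls(tuple(names))

    def name_at(self, rank: str) -> str:
        return self.names[RANKS.index(rank)]

    def is_classified_at(self, rank: str) -> bool:
        return self.name_at(rank) != ""

    def truncate(self, rank: str) -> "Lineage":
        """Lineage with every rank below `rank` blanked."""
        idx = RANKS.index(rank)
        return Lineage(self.names[: idx + 1] + ("",) * (len(RANKS) - idx - 1))

    def format(self, sep: str = ";") -> str:
        return sep.join(
            RANK_PREFIXES[r] + n for r, n in zip(RANKS, self.names)
        )


@dataclass
class AbundanceTable:
    """Samples-by-taxa abundance matrix with per-taxon lineages.

    Parameters
    ----------
    sample_ids : list of str
        Ordered unique sample identifiers (rows).
    taxon_ids : list of str
        Ordered unique taxon identifiers (columns).
    values : ndarray of shape (n_samples, n_taxa)
        Nonnegative abundances.
    lineages : dict mapping taxon id to Lineage
    mode : {"counts", "relative"}
        In relative mode every row must sum to 1 within 1e-9.
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    values: np.ndarray
    lineages: dict[str, Lineage] = field(default_factory=dict)
    mode: str = "counts"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise TableValidationError("values must be 2-D")
        ns, nt = self.values.shape
        if ns == 0 or nt == 0:
            raise TableValidationError("empty table")
        if ns != len(self.sample_ids) or nt != len(self.taxon_ids):
            raise TableValidationError("id lists do not match matrix shape")
        if len(set(self.sample_ids)) != ns:
            raise TableValidationError("duplicate sample ids")
        if len(set(self.taxon_ids)) != nt:
            raise TableValidationError("duplicate taxon ids")
        if np.any(self.values < 0):
            raise TableValidationError("negative abundances")
        if self.mode not in ("counts", "relative"):
            raise TableValidationError(f"unknown mode {self.mode!r}")
        if self.mode == "relative":
            sums = self.values.sum(axis=1)
            if np.any(np.abs(sums - 1.0) > 1e-9):
                bad = self.sample_ids[int(np.argmax(np.abs(sums - 1.0)))]
                raise TableValidationError(
                    f"relative mode but row {bad!r} does not sum to 1"
                )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.values.shape[1]

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def sample_vector(self, sample_id: str) -> np.ndarray:
        return self.values[self.sample_index(sample_id)]

    def select_samples(self, sample_ids: list[str]) -> "AbundanceTable":
        idx = [self.sample_index(s) for s in sample_ids]
        return AbundanceTable(
            list(sample_ids), list(self.taxon_ids), self.values[idx],
            dict(self.lineages), self.mode,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.taxon_ids
        )


@dataclass(frozen=True)
class PairRecord:
    subject_id: str
    sample_before: str
    sample_after: str


@dataclass
class PairedDesign:
    """Subject to (before, after) sample mapping."""

    records: list[PairRecord]

    def __post_init__(self):
        seen: set[str] = set()
        for rec in self.records:
            if rec.sample_before == rec.sample_after:
                raise TableValidationError(
                    f"subject {rec.subject_id}: before == after sample"
                )
            for s in (rec.sample_before, rec.sample_after):
                if s in seen:
                    raise TableValidationError(f"sample {s!r} used twice")
                seen.add(s)
        if len({r.subject_id for r in self.records}) != len(self.records):
            raise TableValidationError("duplicate subject ids")

    @property
    def subject_ids(self) -> list[str]:
        return [r.subject_id for r in self.records]

    @property
    def before_ids(self) -> list[str]:
        return [r.sample_before for r in self.records]

    @property
    def after_ids(self) -> list[str]:
        return [r.sample_after for r in self.records]

    def validate_against(self, table: AbundanceTable) -> None:
        known = set(table.sample_ids)
        for rec in self.records:
            for s in (rec.sample_before, rec.sample_after):
                if s not in known:
                    raise TableValidationError(
                        f"sample {s!r} of subject {rec.subject_id} "
                        "missing from table"
                    )


def load_pairs(path) -> PairedDesign:
    """Read a 3-column TSV manifest (subject_id, sample_before, sample_after)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["subject_id", "sample_before", "sample_after"]
    if list(df.columns[:3]) != required:
        raise TableValidationError(
            f"pairing manifest must have header {required}, got {list(df.columns)}"
        )
    return PairedDesign(
        [PairRecord(r.subject_id, r.sample_before, r.sample_after)
         for r in df.itertuples()]
    )


def write_pairs(design: PairedDesign, path) -> None:
    pd.DataFrame(
        {"subject_id": design.subject_ids,
         "sample_before": design.before_ids,
         "sample_after": design.after_ids}
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# table I/O

def _detect_mode(values: np.ndarray) -> str:
    sums = values.sum(axis=1)
    if np.all(np.abs(sums - 1.0) <= 1e-6):
        return "relative"
    return "counts"


def load_table(path, format: str = "tsv", lineage_sep: str = ";") -> AbundanceTable:
    """Load an abundance table from TSV or BIOM 2.x.

    TSV dialect: taxa rows by sample columns; first column holds the
    prefixed lineage string which doubles as the taxon id.  Mode is
    detected: if every row of the resulting samples-by-taxa matrix sums
    to 1 within 1e-6 the table is marked relative, else counts.
    """
    if format == "tsv":
        return _load_tsv(path, lineage_sep)
    if format == "biom":
        return _load_biom(path, lineage_sep)
    raise ValueError(f"unknown format {format!r}")


def _load_tsv(path, lineage_sep: str) -> AbundanceTable:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dup = [h for h in header if header.count(h) > 1][0]
        raise TableValidationError(f"duplicate sample column {dup!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise TableValidationError(f"empty table in {path}")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise TableValidationError(f"duplicate taxon row {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise TableValidationError(f"duplicate sample column {dup!r}")
    taxon_ids = [str(t) for t in df.index]
    lineages = {}
    for row_num, tid in enumerate(taxon_ids, start=2):
        try:
            lineages[tid] = Lineage.parse(tid, sep=lineage_sep)
        except LineageParseError as exc:
            raise LineageParseError(f"row {row_num} of {path}: {exc}") from exc
    values = df.to_numpy(dtype=float).T  # samples x taxa
    mode = _detect_mode(values)
    if mode == "relative":
        values = values / values.sum(axis=1, keepdims=True)
    return AbundanceTable(
        [str(s) for s in df.columns], taxon_ids, values, lineages, mode
    )


def _load_biom(path, lineage_sep: str) -> AbundanceTable:
    """Minimal BIOM 2.x (HDF5, CSR-by-observation) reader."""
    import h5py
    from scipy.sparse import csr_matrix

    with h5py.File(path, "r") as f:
        obs_ids = [x.decode() for x in f["observation/ids"][:]]
        sample_ids = [x.decode() for x in f["sample/ids"][:]]
        data = f["observation/matrix/data"][:]
        indices = f["observation/matrix/indices"][:]
        indptr = f["observation/matrix/indptr"][:]
        taxonomy = None
        if "observation/metadata/taxonomy" in f:
            taxonomy = f["observation/metadata/taxonomy"][:]
    mat = csr_matrix(
        (data, indices, indptr), shape=(len(obs_ids), len(sample_ids))
    )
    values = np.asarray(mat.todense(), dtype=float).T
    lineages = {}
    for i, tid in enumerate(obs_ids):
        if taxonomy is not None:
            text = lineage_sep.join(x.decode() for x in taxonomy[i])
        else:
            text = tid
        lineages[tid] = Lineage.parse(text, sep=lineage_sep)
    mode = _detect_mode(values)
    if mode == "relative":
        values = values / values.sum(axis=1, keepdims=True)
    return AbundanceTable(sample_ids, obs_ids, values, lineages, mode)


def write_tsv(table: AbundanceTable, path) -> None:
    """Write taxa-rows-by-sample-columns TSV (inverse of ``load_table``)."""
    df = pd.DataFrame(
        table.values.T, index=table.taxon_ids, columns=table.sample_ids
    )
    df.index.name = "lineage"
    df.to_csv(path, sep="\t", float_format="%.12g")


def load_tree(path) -> TreeNode:
    tree = TreeNode.read(str(path), format="newick",
                         convert_underscores=False)
    validate_tree(tree)
    return tree


def validate_tree(tree: TreeNode, taxon_ids=None) -> None:
    names = [t.name for t in tree.tips()]
    if len(set(names)) != len(names):
        raise TableValidationError("duplicate leaf labels in tree")
    for node in tree.traverse(include_self=False):
        if node.length is None or node.length < 0:
            raise TableValidationError(
                f"node {node.name!r} lacks a nonnegative branch length"
            )
    if taxon_ids is not None:
        missing = sorted(set(taxon_ids) - set(names))
        if missing:
            raise TableValidationError(
                f"taxa not found as tree leaves: {missing}"
            )


# ---------------------------------------------------------------------------
# transforms

def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Divide each row by its sum; requires counts mode, no all-zero sample."""
    if table.mode != "counts":
        raise TableValidationError("to_relative expects a counts-mode table")
    sums = table.values.sum(axis=1)
    if np.any(sums == 0):
        bad = table.sample_ids[int(np.argmin(sums))]
        raise TableValidationError(f"all-zero sample {bad!r}")
    return AbundanceTable(
        list(table.sample_ids), list(table.taxon_ids),
        table.values / sums[:, None], dict(table.lineages), "relative",
    )


def aggregate_rank(table: AbundanceTable, rank: str,
                   sep: str = ";") -> AbundanceTable:
    """Sum taxa sharing the named rank (and all higher ranks).

    Taxa unclassified at `rank` are pooled per nearest classified ancestor
    under a name suffixed with ``_u``.  `sep` is the delimiter used when
    formatting the aggregated taxon ids.
    """
    if rank not in RANKS:
        raise TableValidationError(f"unknown rank {rank!r}")
    rank_idx = RANKS.index(rank)
    if not table.lineages:
        raise TableValidationError("table has no lineages")

    group_keys: list[tuple] = []
    group_lineages: dict[tuple, Lineage] = {}
    for tid in table.taxon_ids:
        lin = table.lineages[tid]
        names = list(lin.names[: rank_idx + 1])
        if names[rank_idx] == "":
            # pool under nearest classified ancestor with "_u" suffix
            anc = ""
            for j in range(rank_idx - 1, -1, -1):
                if names[j] != "":
                    anc = names[j]
                    break
            names[rank_idx] = anc + "_u"
        key = tuple(names)
        group_keys.append(key)
        if key not in group_lineages:
            group_lineages[key] = Lineage(
                tuple(names) + ("",) * (len(RANKS) - rank_idx - 1)
            )

    ordered = list(dict.fromkeys(group_keys))
    cols = {key: i for i, key in enumerate(ordered)}
    values = np.zeros((table.n_samples, len(ordered)))
    for j, key in enumerate(group_keys):
        values[:, cols[key]] += table.values[:, j]

    new_ids = [group_lineages[key].format(sep) for key in ordered]
    new_lineages = {group_lineages[key].format(sep): group_lineages[key]
                    for key in ordered}
    if table.mode == "relative":
        values = values / values.sum(axis=1, keepdims=True)
    return AbundanceTable(
        list(table.sample_ids), new_ids, values, new_lineages, table.mode
    )


def prevalence_filter(
    table: AbundanceTable, min_frac: float = 0.002, min_samples: int = 15
) -> tuple[AbundanceTable, list[str]]:
    """Retain taxa with relative abundance >= min_frac in >= min_samples samples.

    Returns the filtered table and the list of removed taxon ids.
    """
    if table.mode != "relative":
        raise TableValidationError("prevalence_filter expects relative mode")
    if min_samples > table.n_samples:
        raise TableValidationError(
            f"min_samples={min_samples} exceeds {table.n_samples} samples"
        )
    hits = (table.values >= min_frac).sum(axis=0)
    keep = hits >= min_samples
    if not keep.any():
        raise TableValidationError("prevalence filter removed every taxon")
    kept_ids = [t for t, k in zip(table.taxon_ids, keep) if k]
    removed = [t for t, k in zip(table.taxon_ids, keep) if not k]
    values = table.values[:, keep]
    # renormalize so relative-mode invariant holds after dropping taxa
    values = values / values.sum(axis=1, keepdims=True)
    lineages = {t: table.lineages[t] for t in kept_ids
                if t in table.lineages}
    return (
        AbundanceTable(list(table.sample_ids), kept_ids, values, lineages,
                       "relative"),
        removed,
    )


def bf_ratio(
    table: AbundanceTable,
    numerator_phylum: str = "Bacteroidetes",
    denominator_phylum: str = "Firmicutes",
) -> np.ndarray:
    """Per-sample Bacteroidetes:Firmicutes abundance ratio.

    Samples whose Firmicutes sum is zero get NaN (undefined, not an error).
    """
    num_cols, den_cols = [], []
    for j, tid in enumerate(table.taxon_ids):
        phylum = table.lineages[tid].name_at("phylum")
        if phylum == numerator_phylum:
            num_cols.append(j)
        elif phylum == denominator_phylum:
            den_cols.append(j)
    if not num_cols or not den_cols:
        raise TableValidationError(
            f"phyla {numerator_phylum!r}/{denominator_phylum!r} not both present"
        )
    num = table.values[:, num_cols].sum(axis=1)
    den = table.values[:, den_cols].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return ratio


def concat_tables(a: AbundanceTable, b: AbundanceTable) -> AbundanceTable:
    """Stack two tables with identical taxa and mode along the sample axis."""
    if a.taxon_ids != b.taxon_ids:
        raise TableValidationError("taxon sets differ")
    if a.mode != b.mode:
        raise TableValidationError("modes differ")
    if set(a.sample_ids) & set(b.sample_ids):
        raise TableValidationError("overlapping sample ids")
    return AbundanceTable(
        list(a.sample_ids) + list(b.sample_ids),
        list(a.taxon_ids),
        np.vstack([a.values, b.values]),
        dict(a.lineages),
        a.mode,
    )
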