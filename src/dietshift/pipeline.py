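"""End-to-end orchestration: filter -> distances -> typing -> response ->
PERMANOVA -> compositional stats, with reproducible run metadata.

``run_pipeline`` is a pure function of (input files, config, seed): the
summary JSON is byte-identical across reruns with the same config.  Stage
timings go to the JSONL run log, never into the summary.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, data_model, distances, response, stats
from . import typing as typing_mod
from .permanova_power import permanova


@dataclass
class RunConfig:
    table: str
    pairs: str
    tree: str | None = None
    edge_list: str | None = None
    out_dir: str = "dietshift_run"
    lineage_sep: str = ";"
    rank: str = "genus"
    filter_min_frac: float = 0.002
    filter_min_samples: int = 15
    metric: str = "gunifrac"
    unifrac_alpha: float = 0.5
    k_min: int = 2
    k_max: int = 10
    n_bootstrap: int = 100
    stability_threshold: float = 0.8
    n_permutations: int = 2000
    marker_alpha: float = 0.05
    classifier_splits: int = 10
    train_fraction: float = 0.7
    seed: int = 0

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(**payload)

    def validate(self) -> None:
        for name in ("table", "pairs"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} file {p!r} does not exist")
        if self.metric == "gunifrac":
            if self.tree is None:
                raise ValueError("metric=gunifrac requires a tree")
            if not Path(self.tree).exists():
                raise FileNotFoundError(f"tree file {self.tree!r} missing")
        if self.edge_list is not None and not Path(self.edge_list).exists():
            raise FileNotFoundError(f"edge list {self.edge_list!r} missing")


@dataclass
class RunReport:
    summary: dict
    outputs: dict[str, str]
    stages_completed: list[str] = field(default_factory=list)


def _derive_seed(master: int, counter: int) -> int:
    # documented counter scheme: one master seed, stage seeds spaced apart
    return master * 100_003 + counter


def _mean_sd(x) -> list[float]:
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    return [round(float(x.mean()), 6), round(float(x.std(ddof=1)), 6)]


def run_pipeline(config: RunConfig) -> RunReport:
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run_log.jsonl"
    log_fh = open(log_path, "w")
    outputs: dict[str, str] = {}
    stages: list[str] = []
    summary: dict = {"version": __version__,
                     "config": {k: v for k, v in vars(config).items()}}

    def log(stage: str, **payload):
        log_fh.write(json.dumps({"stage": stage, **payload}) + "\n")
        log_fh.flush()

    def run_stage(name, fn):
        t0 = time.time()
        try:
            result = fn()
        except Exception as exc:
            log(name, status="failed", error=str(exc),
                seconds=round(time.time() - t0, 3))
            log_fh.close()
            raise RuntimeError(
                f"pipeline stage {name!r} failed after stages {stages}: {exc}"
            ) from exc
        stages.append(name)
        log(name, status="ok", seconds=round(time.time() - t0, 3))
        return result

    # ---- load ------------------------------------------------------------
    def _load():
        table = data_model.load_table(config.table,
                                      lineage_sep=config.lineage_sep)
        design = data_model.load_pairs(config.pairs)
        design.validate_against(table)
        tree = data_model.load_tree(config.tree) if config.tree else None
        return table, design, tree

    table, design, tree = run_stage("load", _load)

    # ---- preprocess ------------------------------------------------------
    def _preprocess():
        t = data_model.aggregate_rank(table, config.rank,
                                      sep=config.lineage_sep)
        counts = t if t.mode == "counts" else None
        rel = data_model.to_relative(t) if t.mode == "counts" else t
        rel, removed = data_model.prevalence_filter(
            rel, config.filter_min_frac, config.filter_min_samples
        )
        if counts is not None:
            keep = rel.taxon_ids
            idx = [counts.taxon_ids.index(x) for x in keep]
            counts = data_model.AbundanceTable(
                list(counts.sample_ids), list(keep),
                counts.values[:, idx],
                {x: counts.lineages[x] for x in keep}, "counts",
            )
        return rel, counts, removed

    rel, counts, removed = run_stage("preprocess", _preprocess)
    summary["n_samples"] = rel.n_samples
    summary["n_taxa_after_filter"] = rel.n_taxa
    summary["n_taxa_removed"] = len(removed)

    # ---- typing ----------------------------------------------------------
    def _typing():
        return typing_mod.permatype(
            rel,
            n_bootstrap=config.n_bootstrap,
            threshold=config.stability_threshold,
            seed=_derive_seed(config.seed, 1),
            k_range=range(config.k_min, config.k_max + 1),
        )

    perma = run_stage("typing", _typing)
    summary["k_enterotype"] = perma.base.k
    summary["enterotype_sizes"] = perma.base.cluster_sizes()
    core_sizes = {
        c: sum(1 for v in perma.core_labels.values() if v == c)
        for c in range(1, perma.base.k + 1)
    }
    summary["permatype_core_sizes"] = core_sizes
    summary["permatype_unclassified"] = len(perma.unclassified)

    labels_path = out / "typing_labels.tsv"
    with open(labels_path, "w") as fh:
        fh.write("sample_id\tenterotype\tstability\tpermatype\n")
        for i, sid in enumerate(perma.base.sample_ids):
            core = perma.core_labels.get(sid, "")
            fh.write(f"{sid}\t{perma.base.labels[i]}\t"
                     f"{perma.stability[i]:.4f}\t{core}\n")
    outputs["typing_labels"] = str(labels_path)

    # ---- response --------------------------------------------------------
    def _response():
        diss, dropped = response.paired_dissimilarity(
            rel, tree, design, metric=config.metric,
            alpha=config.unifrac_alpha,
        )
        res = response.cluster_response(
            diss, k_range=range(config.k_min, config.k_max + 1)
        )
        return diss, dropped, res

    diss, dropped_subjects, resp = run_stage("response", _response)
    summary["n_subjects_paired"] = int(len(diss))
    summary["n_subjects_dropped"] = len(dropped_subjects)
    summary["k_response"] = resp.k_selected
    summary["response_binary"] = resp.binary
    summary["response_group_means"] = {
        str(c): round(v, 6) for c, v in resp.group_means.items()
    }
    if resp.binary:
        counts_by = resp.labels.value_counts()
        summary["response_group_sizes"] = {
            lab: int(counts_by[lab]) for lab in sorted(counts_by.index)
        }
    diss_path = out / "response_dissimilarity.tsv"
    frame = diss.to_frame()
    if resp.binary:
        frame["label"] = resp.labels
    frame.to_csv(diss_path, sep="\t")
    outputs["response_dissimilarity"] = str(diss_path)

    # ---- baseline markers + classifier -----------------------------------
    if resp.binary:
        def _markers():
            baseline = rel.select_samples(
                [r.sample_before for r in design.records
                 if r.subject_id in diss.index]
            )
            y = resp.labels.loc[
                [r.subject_id for r in design.records
                 if r.subject_id in diss.index]
            ].to_numpy()
            markers = response.group_marker_test(baseline, y)
            sig = markers[markers["adjusted_p"] < config.marker_alpha]
            ev = None
            if len(sig) >= 1:
                cols = [baseline.taxon_ids.index(t) for t in sig.index]
                ev = response.evaluate_baseline_classifier(
                    baseline.values[:, cols], y,
                    n_splits=config.classifier_splits,
                    train_fraction=config.train_fraction,
                    seed=_derive_seed(config.seed, 2),
                )
            return markers, ev

        markers, clf_eval = run_stage("markers", _markers)
        summary["n_baseline_markers"] = int(
            (markers["adjusted_p"] < config.marker_alpha).sum()
        )
        summary["classifier_mean_auc"] = (
            round(clf_eval.mean_auc, 6) if clf_eval is not None else None
        )
        markers.to_csv(out / "baseline_markers.tsv", sep="\t",
                       float_format="%.6g")
        outputs["baseline_markers"] = str(out / "baseline_markers.tsv")

    # ---- PERMANOVA before vs after ---------------------------------------
    def _permanova():
        dm = distances.pairwise_matrix(
            rel, config.metric, tree=tree, alpha=config.unifrac_alpha
        )
        groups = []
        before = {r.sample_before for r in design.records}
        for sid in rel.sample_ids:
            groups.append("before" if sid in before else "after")
        return permanova(
            dm, groups, n_permutations=config.n_permutations,
            pairing=design, seed=_derive_seed(config.seed, 3),
        )

    pa = run_stage("permanova", _permanova)
    summary["permanova"] = {
        "pseudo_F": round(pa.pseudo_F, 6),
        "R2": round(pa.R2, 6),
        "p_value": round(pa.p_value, 8),
        "omega2": round(pa.omega2, 8),
        "n_permutations": pa.n_permutations,
        "scheme": pa.scheme,
    }

    # ---- compositional summaries -----------------------------------------
    def _stats():
        before_ids = [r.sample_before for r in design.records]
        after_ids = [r.sample_after for r in design.records]
        rel_b = rel.select_samples(before_ids)
        rel_a = rel.select_samples(after_ids)
        bf_b = data_model.bf_ratio(rel_b)
        bf_a = data_model.bf_ratio(rel_a)
        sh_b = [stats.shannon(v) for v in rel_b.values]
        sh_a = [stats.shannon(v) for v in rel_a.values]
        clr_table = None
        if counts is not None:
            cb = counts.select_samples(before_ids)
            ca = counts.select_samples(after_ids)
            clr_table = stats.paired_clr_test(cb, ca, design)
        return bf_b, bf_a, sh_b, sh_a, clr_table

    bf_b, bf_a, sh_b, sh_a, clr_table = run_stage("stats", _stats)
    summary["bf_ratio_before"] = _mean_sd(bf_b)
    summary["bf_ratio_after"] = _mean_sd(bf_a)
    summary["shannon_before"] = _mean_sd(sh_b)
    summary["shannon_after"] = _mean_sd(sh_a)
    if clr_table is not None:
        summary["n_paired_clr_significant"] = int(
            (clr_table["adjusted_p"] < 0.05).sum()
        )
        clr_table.to_csv(out / "paired_clr_test.tsv", sep="\t",
                         float_format="%.6g")
        outputs["paired_clr_test"] = str(out / "paired_clr_test.tsv")

    # ---- permatype transitions -------------------------------------------
    def _transitions():
        before_labels = {}
        after_labels = {}
        for rec in design.records:
            if rec.sample_before in perma.core_labels:
                before_labels[rec.sample_before] = perma.core_labels[
                    rec.sample_before]
            if rec.sample_after in perma.core_labels:
                after_labels[rec.sample_after] = perma.core_labels[
                    rec.sample_after]
        results = {}
        for c in range(1, perma.base.k + 1):
            try:
                r = typing_mod.transition_analysis(
                    before_labels, after_labels, design, focus_cluster=c
                )
            except ValueError:
                continue
            results[str(c)] = round(r["fisher_p"], 8)
        return results

    transitions = run_stage("transitions", _transitions)
    summary["transition_fisher_p"] = transitions

    # ---- cooperatives ----------------------------------------------------
    if config.edge_list is not None:
        def _coops():
            edges = stats.load_edge_list(config.edge_list)
            coops = stats.cooperatives(edges, table=rel)
            ab = stats.cooperative_abundance(coops, rel)
            return coops, ab

        coops, coop_ab = run_stage("cooperatives", _coops)
        summary["cooperatives"] = {
            name: len(members) for name, members in coops.components.items()
        }
        coop_ab.to_csv(out / "cooperative_abundance.tsv", sep="\t",
                       float_format="%.6g")
        outputs["cooperative_abundance"] = str(out / "cooperative_abundance.tsv")

    summary_path = out / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    outputs["summary"] = str(summary_path)
    log("done", stages=stages)
    log_fh.close()
    return RunReport(summary=summary, outputs=outputs,
                     stages_completed=stages)
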