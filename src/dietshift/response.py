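"""Responder / non-responder discovery and baseline predictability.

Subjects are clustered by the dissimilarity between their paired samples;
with two clusters, the lower-mean cluster is labelled ``non_responder``.
Baseline predictability is scored with repeated stratified 70/30 splits of a
random-forest classifier.  Note that, as in the protocol this reproduces,
feature selection happens on the full data set before splitting, which is
optimistically biased.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve

from .data_model import AbundanceTable, PairedDesign, TableValidationError
from .distances import (
    BranchProfile,
    DistanceMatrix,
    bray_curtis,
    jsd_distance,
)
from .stats import bh_adjust
from .typing import mean_silhouette, pam

RESPONDER = "responder"
NON_RESPONDER = "non_responder"


@dataclass
class ResponseResult:
    dissimilarities: pd.Series        # per subject
    k_selected: int
    cluster_labels: pd.Series         # 1..k per subject
    labels: pd.Series | None          # responder/non_responder iff k == 2
    group_means: dict
    group_sds: dict
    silhouette_per_k: dict[int, float]
    binary: bool


@dataclass
class ClassifierEval:
    n_splits: int
    train_fraction: float
    aucs: list[float]
    mean_auc: float
    roc_points: list
    seed: int
    n_redraws: int
    classifier_params: dict = field(default_factory=dict)


def paired_dissimilarity(
    table: AbundanceTable,
    tree,
    design: PairedDesign,
    metric: str = "gunifrac",
    alpha: float = 0.5,
) -> tuple[pd.Series, list[str]]:
    """Distance between each subject's before and after profiles.

    Subjects with a missing pair member are dropped and reported in the
    second return value.
    """
    if table.mode != "relative":
        raise TableValidationError("paired_dissimilarity expects relative mode")
    known = set(table.sample_ids)
    kept, dropped = [], []
    for rec in design.records:
        if rec.sample_before in known and rec.sample_after in known:
            kept.append(rec)
        else:
            dropped.append(rec.subject_id)
    if not kept:
        raise TableValidationError("no subject has both samples in the table")

    values = {}
    if metric == "gunifrac":
        profile = BranchProfile(tree, table.taxon_ids)
        bmat = profile.branch_abundances(table.values)
        for rec in kept:
            i = table.sample_index(rec.sample_before)
            j = table.sample_index(rec.sample_after)
            values[rec.subject_id] = profile.pair_distance(
                bmat[i], bmat[j], alpha
            )
    elif metric in ("jsd", "bray_curtis"):
        fn = jsd_distance if metric == "jsd" else bray_curtis
        for rec in kept:
            values[rec.subject_id] = fn(
                table.sample_vector(rec.sample_before),
                table.sample_vector(rec.sample_after),
            )
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return pd.Series(values, name="dissimilarity"), dropped


def cluster_response(
    dissimilarities: pd.Series, k_range: range = range(2, 11)
) -> ResponseResult:
    """PAM over the scalar dissimilarities; k by maximal mean silhouette.

    With k = 2 the lower-mean cluster is ``non_responder``; with k > 2 no
    binary labelling is emitted and ``binary`` is False.
    """
    x = dissimilarities.to_numpy(dtype=float)
    n = len(x)
    if np.ptp(x) == 0:
        raise ValueError("all dissimilarities identical; no cluster structure")
    ks = [k for k in k_range if 2 <= k <= n - 1]
    if n < max(k_range) + 1:
        raise ValueError(
            f"need at least {max(k_range) + 1} subjects, got {n}"
        )
    dist = DistanceMatrix(
        list(dissimilarities.index), np.abs(x[:, None] - x[None, :])
    )
    sil = {}
    fits = {}
    for k in ks:
        res = pam(dist, k)
        fits[k] = res
        sil[k] = mean_silhouette(dist, res.labels)
    k_sel = max(ks, key=lambda k: (sil[k], -k))
    fit = fits[k_sel]
    cluster_labels = pd.Series(fit.labels, index=dissimilarities.index)
    group_means = {
        c: float(x[fit.labels == c].mean()) for c in range(1, k_sel + 1)
    }
    group_sds = {
        c: float(x[fit.labels == c].std(ddof=1)) for c in range(1, k_sel + 1)
    }
    if k_sel == 2:
        low = min(group_means, key=group_means.get)
        labels = cluster_labels.map(
            lambda c: NON_RESPONDER if c == low else RESPONDER
        )
        binary = True
    else:
        labels = None
        binary = False
    return ResponseResult(
        dissimilarities=dissimilarities,
        k_selected=k_sel,
        cluster_labels=cluster_labels,
        labels=labels,
        group_means=group_means,
        group_sds=group_sds,
        silhouette_per_k=sil,
        binary=binary,
    )


def _stratified_split(y: np.ndarray, train_fraction: float,
                      rng: np.random.Generator):
    train_idx, test_idx = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        n_train = int(round(train_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train_idx.extend(idx[:n_train])
        test_idx.extend(idx[n_train:])
    return np.asarray(train_idx), np.asarray(test_idx)


def evaluate_baseline_classifier(
    features: np.ndarray,
    labels,
    n_splits: int = 10,
    train_fraction: float = 0.7,
    seed: int = 0,
    n_estimators: int = 100,
) -> ClassifierEval:
    """Mean ROC AUC of a random forest over repeated stratified 70/30 splits.

    Deterministic given `seed`.  Splits with a single-class test set are
    re-drawn and counted; more than 50% re-draws is an error.
    """
    features = np.asarray(features, dtype=float)
    y_raw = np.asarray(labels)
    classes = np.unique(y_raw)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    y = (y_raw == classes[1]).astype(int)
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need at least 2 samples per class")

    rng = np.random.default_rng(seed)
    aucs, rocs = [], []
    n_redraws = 0
    max_redraws = max(1, n_splits // 2)
    for split in range(n_splits):
        while True:
            tr, te = _stratified_split(y, train_fraction, rng)
            if len(np.unique(y[te])) == 2:
                break
            n_redraws += 1
            if n_redraws > max_redraws:
                raise RuntimeError("too many degenerate splits")
        clf = RandomForestClassifier(
            n_estimators=n_estimators,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        clf.fit(features[tr], y[tr])
        score = clf.predict_proba(features[te])[:, 1]
        aucs.append(float(roc_auc_score(y[te], score)))
        fpr, tpr, _ = roc_curve(y[te], score)
        rocs.append(np.column_stack([fpr, tpr]))
    return ClassifierEval(
        n_splits=n_splits,
        train_fraction=train_fraction,
        aucs=aucs,
        mean_auc=float(np.mean(aucs)),
        roc_points=rocs,
        seed=seed,
        n_redraws=n_redraws,
        classifier_params={"model": "RandomForestClassifier",
                           "n_estimators": n_estimators},
    )


def group_marker_test(
    table_baseline: AbundanceTable, labels
) -> pd.DataFrame:
    """Per-taxon two-sided Mann-Whitney test between two groups, BH adjusted.

    `labels` aligns with the table's samples.  Returns p, adjusted_p and the
    sign of the median difference (group2 minus group1, groups in sorted
    label order).  Constant taxa get p = 1 by convention.
    """
    y = np.asarray(labels)
    if len(y) != table_baseline.n_samples:
        raise ValueError("labels length mismatch")
    groups = np.unique(y)
    if len(groups) != 2:
        raise ValueError("need exactly two groups")
    a = table_baseline.values[y == groups[0]]
    b = table_baseline.values[y == groups[1]]
    pvals = np.ones(table_baseline.n_taxa)
    direction = np.zeros(table_baseline.n_taxa, dtype=int)
    for j in range(table_baseline.n_taxa):
        col_a, col_b = a[:, j], b[:, j]
        pooled = np.concatenate([col_a, col_b])
        if np.ptp(pooled) == 0:
            continue
        # exact null when group sizes are small and values tie-free
        method = ("exact" if max(len(col_a), len(col_b)) <= 25
                  and len(np.unique(pooled)) == len(pooled) else "asymptotic")
        res = sps.mannwhitneyu(col_b, col_a, alternative="two-sided",
                               method=method)
        pvals[j] = float(res.pvalue)
        direction[j] = int(np.sign(np.median(col_b) - np.median(col_a)))
    return pd.DataFrame(
        {"p": pvals, "adjusted_p": bh_adjust(pvals), "direction": direction},
        index=table_baseline.taxon_ids,
    )
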