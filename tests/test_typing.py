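import itertools
import math

import numpy as np
import pytest

from dietshift.data_model import AbundanceTable, to_relative
from dietshift.distances import DistanceMatrix, pairwise_matrix
from dietshift.typing import (
    calinski_harabasz,
    driver_taxa,
    enterotype,
    mean_silhouette,
    pam,
    permatype,
    transition_analysis,
)
from tests.conftest import make_design


def random_distance_matrix(n, rng):
    pts = rng.random((n, 2)) * 10
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    return DistanceMatrix([f"s{i}" for i in range(n)], d)


def exhaustive_pam_cost(d, k):
    """Oracle: minimal assignment cost over all medoid subsets of size k."""
    n = d.shape[0]
    best = np.inf
    for medoids in itertools.combinations(range(n), k):
        cost = d[:, medoids].min(axis=1).sum()
        best = min(best, cost)
    return best


class TestPam:
    def test_two_tight_pairs(self):
        d = np.array([
            [0.0, 0.1, 9.0, 9.1],
            [0.1, 0.0, 9.2, 9.0],
            [9.0, 9.2, 0.0, 0.1],
            [9.1, 9.0, 0.1, 0.0],
        ])
        res = pam(DistanceMatrix(list("abcd"), d), 2)
        assert res.labels[0] == res.labels[1]
        assert res.labels[2] == res.labels[3]
        assert res.labels[0] != res.labels[2]

    def test_k_equals_n(self):
        dm = random_distance_matrix(5, np.random.default_rng(0))
        res = pam(dm, 5)
        assert res.cost == 0.0
        assert sorted(res.medoids) == sorted(dm.ids)

    def test_k_out_of_range(self):
        dm = random_distance_matrix(5, np.random.default_rng(0))
        with pytest.raises(ValueError):
            pam(dm, 1)
        with pytest.raises(ValueError):
            pam(dm, 6)

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 9))
        k = int(rng.integers(2, 4))
        dm = random_distance_matrix(n, rng)
        res = pam(dm, k)
        oracle = exhaustive_pam_cost(dm.data, k)
        assert res.cost == pytest.approx(oracle, abs=1e-9)

    def test_deterministic(self):
        dm = random_distance_matrix(20, np.random.default_rng(42))
        r1, r2 = pam(dm, 3), pam(dm, 3)
        assert r1.medoids == r2.medoids
        assert (r1.labels == r2.labels).all()


class TestCalinskiHarabasz:
    def test_separated_beats_random(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0, 0.5, (15, 2)),
                         rng.normal(10, 0.5, (15, 2))])
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dm = DistanceMatrix([f"s{i}" for i in range(30)], d)
        truth = np.repeat([1, 2], 15)
        ch_true = calinski_harabasz(dm, truth)
        for _ in range(10):
            ch_rand = calinski_harabasz(dm, rng.permutation(truth))
            assert ch_true > ch_rand

    def test_all_singletons_error(self):
        dm = random_distance_matrix(4, np.random.default_rng(1))
        with pytest.raises(ValueError):
            calinski_harabasz(dm, np.arange(1, 5))

    def test_matches_direct_coordinates(self):
        # Euclidean data: distance-path CH equals CH from raw coordinates,
        # computed here from the scatter definition
        rng = np.random.default_rng(7)
        pts = np.vstack([rng.normal(0, 1, (10, 3)),
                         rng.normal(4, 1, (12, 3))])
        labels = np.array([1] * 10 + [2] * 12)
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dm = DistanceMatrix([f"s{i}" for i in range(22)], d)
        n, k = 22, 2
        centroid = pts.mean(axis=0)
        ssb = ssw = 0.0
        for c in (1, 2):
            sub = pts[labels == c]
            mu = sub.mean(axis=0)
            ssb += len(sub) * ((mu - centroid) ** 2).sum()
            ssw += ((sub - mu) ** 2).sum()
        oracle = (ssb / (k - 1)) / (ssw / (n - k))
        assert calinski_harabasz(dm, labels) == pytest.approx(oracle,
                                                              rel=1e-8)


class TestMeanSilhouette:
    def test_two_tight_clusters(self):
        rng = np.random.default_rng(0)
        pts = np.concatenate([rng.normal(0, 0.05, 10),
                              rng.normal(5, 0.05, 10)])
        d = np.abs(pts[:, None] - pts[None, :])
        dm = DistanceMatrix([f"s{i}" for i in range(20)], d)
        assert mean_silhouette(dm, np.repeat([1, 2], 10)) > 0.9

    def test_random_labels_near_zero(self):
        rng = np.random.default_rng(1)
        dm = random_distance_matrix(40, rng)
        # permutation-mean oracle: average silhouette over random labelings
        vals = [mean_silhouette(dm, rng.integers(1, 3, size=40))
                for _ in range(30)]
        assert abs(np.mean(vals)) < 0.1

    def test_singleton_contributes_zero(self):
        d = np.array([[0.0, 1.0, 5.0], [1.0, 0.0, 5.0], [5.0, 5.0, 0.0]])
        dm = DistanceMatrix(list("abc"), d)
        from sklearn.metrics import silhouette_samples

        s = silhouette_samples(d, np.array([1, 1, 2]), metric="precomputed")
        assert s[2] == 0.0
        assert mean_silhouette(dm, [1, 1, 2]) == pytest.approx(s.mean())


def planted_table(n_per_type, centroids, conc, rng):
    k, nt = centroids.shape
    rows, labels = [], []
    for t in range(k):
        rows.append(rng.dirichlet(conc * centroids[t], size=n_per_type))
        labels += [t + 1] * n_per_type
    values = np.vstack(rows)
    table = AbundanceTable(
        [f"s{i}" for i in range(values.shape[0])],
        [f"t{j}" for j in range(nt)], values, {}, "relative",
    )
    return table, np.array(labels)


class TestEnterotype:
    def test_recovers_three_planted_types(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(0)
        centroids = rng.dirichlet(np.ones(20), size=3) + 0.01
        centroids /= centroids.sum(1, keepdims=True)
        table, truth = planted_table(25, centroids, 500, rng)
        res = enterotype(table)
        assert res.k == 3
        assert adjusted_rand_score(truth, res.labels) >= 0.95

    def test_recovers_two_planted_types(self):
        from sklearn.metrics import adjusted_rand_score

        rng = np.random.default_rng(4)
        centroids = rng.dirichlet(np.ones(15), size=2) + 0.01
        centroids /= centroids.sum(1, keepdims=True)
        table, truth = planted_table(30, centroids, 400, rng)
        res = enterotype(table)
        assert res.k == 2
        assert adjusted_rand_score(truth, res.labels) >= 0.95

    def test_degenerate_duplicates(self):
        # near-identical samples: must either raise or return a boundary k,
        # never crash with an unrelated error
        rng = np.random.default_rng(1)
        base = rng.dirichlet(np.ones(10))
        values = np.tile(base, (12, 1)) + rng.normal(0, 1e-9, (12, 10))
        values = np.abs(values)
        values /= values.sum(1, keepdims=True)
        table = AbundanceTable([f"s{i}" for i in range(12)],
                               [f"t{j}" for j in range(10)], values, {},
                               "relative")
        try:
            res = enterotype(table)
            assert res.k in (min(range(2, 11)), max(range(2, 11)))
        except (ValueError, FloatingPointError):
            pass

    def test_taxon_permutation_invariance(self):
        rng = np.random.default_rng(5)
        centroids = rng.dirichlet(np.ones(12), size=3) + 0.01
        centroids /= centroids.sum(1, keepdims=True)
        table, _ = planted_table(10, centroids, 300, rng)
        perm = rng.permutation(12)
        table2 = AbundanceTable(
            list(table.sample_ids), [table.taxon_ids[j] for j in perm],
            table.values[:, perm], {}, "relative",
        )
        r1, r2 = enterotype(table), enterotype(table2)
        assert r1.k == r2.k
        assert (r1.labels == r2.labels).all()


class TestPermatype:
    def _separated_table(self, rng, n_per_type=20):
        centroids = rng.dirichlet(np.ones(15), size=3) * 5 + 0.02
        centroids /= centroids.sum(1, keepdims=True)
        return planted_table(n_per_type, centroids, 800, rng)

    def test_separated_types_all_stable(self):
        rng = np.random.default_rng(0)
        table, _ = self._separated_table(rng)
        res = permatype(table, n_bootstrap=40, threshold=0.8, seed=1)
        assert res.unclassified == []
        assert np.all(res.stability >= 0.8)

    def test_core_labels_restrict_base(self):
        rng = np.random.default_rng(2)
        table, _ = self._separated_table(rng)
        res = permatype(table, n_bootstrap=30, threshold=0.9, seed=3)
        base = dict(zip(res.base.sample_ids, res.base.labels))
        for sid, lab in res.core_labels.items():
            assert lab == base[sid]
        assert set(res.core_labels) | set(res.unclassified) == set(
            res.base.sample_ids)
        assert not (set(res.core_labels) & set(res.unclassified))

    def test_threshold_boundaries(self):
        rng = np.random.default_rng(3)
        table, _ = self._separated_table(rng, n_per_type=12)
        res0 = permatype(table, n_bootstrap=20, threshold=0.0, seed=1)
        assert res0.unclassified == []
        res2 = permatype(table, n_bootstrap=20, threshold=1.01, seed=1)
        assert sorted(res2.unclassified) == sorted(res2.base.sample_ids)

    def test_mixture_samples_less_stable(self, mixture_cohort):
        cohort = mixture_cohort
        rel = to_relative(cohort.table_before)
        res = permatype(rel, n_bootstrap=60, threshold=0.8, seed=5)
        mix = np.array(cohort.truth.mixture)
        stab = res.stability
        assert stab[mix].mean() < stab[~mix].mean()
        uncls = np.isin(rel.sample_ids, res.unclassified)
        rate_mix = uncls[mix].mean()
        rate_pure = max(uncls[~mix].mean(), 1e-12)
        assert rate_mix >= 2 * rate_pure

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(6)
        table, _ = self._separated_table(rng, n_per_type=10)
        perm = rng.permutation(table.n_samples)
        table2 = AbundanceTable(
            [table.sample_ids[i] for i in perm], list(table.taxon_ids),
            table.values[perm], {}, "relative",
        )
        r1 = permatype(table, n_bootstrap=25, seed=9)
        r2 = permatype(table2, n_bootstrap=25, seed=9)
        s1 = dict(zip(r1.base.sample_ids, r1.stability))
        s2 = dict(zip(r2.base.sample_ids, r2.stability))
        assert s1 == s2

    def test_min_bootstrap(self):
        rng = np.random.default_rng(0)
        table, _ = self._separated_table(rng, n_per_type=5)
        with pytest.raises(ValueError):
            permatype(table, n_bootstrap=5)


class TestDriverTaxa:
    def test_planted_dominant_genus_first(self):
        rng = np.random.default_rng(0)
        centroids = np.full((2, 10), 0.05)
        centroids[0, 0] = 0.55
        centroids[1, 5] = 0.55
        centroids /= centroids.sum(1, keepdims=True)
        table, truth = planted_table(15, centroids, 600, rng)
        res = enterotype(table, k_range=range(2, 4))
        drivers = driver_taxa(res, table, top_m=3)
        tops = {c: drivers[c][0][0] for c in drivers}
        assert set(tops.values()) == {"t0", "t5"}

    def test_identical_clusters_scores_near_zero(self):
        rng = np.random.default_rng(1)
        half = rng.dirichlet(np.ones(8), size=10)
        values = np.vstack([half, half])  # cluster 2 duplicates cluster 1
        table = AbundanceTable([f"s{i}" for i in range(20)],
                               [f"t{j}" for j in range(8)], values, {},
                               "relative")
        from dietshift.typing import TypingResult

        labels = np.repeat([1, 2], 10)
        res = TypingResult(2, labels, ["s0", "s10"], list(table.sample_ids),
                           0.0)
        drivers = driver_taxa(res, table, top_m=8)
        assert all(abs(score) < 1e-12 for c in drivers
                   for _, score in drivers[c])

    def test_top_m_larger_than_taxa(self):
        rng = np.random.default_rng(2)
        centroids = rng.dirichlet(np.ones(6), size=2) + 0.05
        centroids /= centroids.sum(1, keepdims=True)
        table, _ = planted_table(10, centroids, 300, rng)
        res = enterotype(table, k_range=range(2, 3))
        drivers = driver_taxa(res, table, top_m=100)
        assert all(len(v) == 6 for v in drivers.values())


class TestTransitionAnalysis:
    def test_maximal_association_matches_hypergeometric(self):
        # 5 focus subjects all stay, 5 others all move
        design = make_design(10)
        before = {}
        after = {}
        for i in range(10):
            if i < 5:
                before[f"S{i}_B"] = 1
                after[f"S{i}_A"] = 1      # stayed
            else:
                before[f"S{i}_B"] = 2
                after[f"S{i}_A"] = 1      # moved
        res = transition_analysis(before, after, design, focus_cluster=1)
        np.testing.assert_array_equal(res["contingency"],
                                      [[5, 0], [0, 5]])
        # oracle: two-sided Fisher p by explicit hypergeometric enumeration
        def hyper_pmf(a, r1, r2, c1):
            return (math.comb(r1, a) * math.comb(r2, c1 - a)
                    / math.comb(r1 + r2, c1))

        p_obs = hyper_pmf(5, 5, 5, 5)
        p_two = sum(hyper_pmf(a, 5, 5, 5) for a in range(6)
                    if hyper_pmf(a, 5, 5, 5) <= p_obs + 1e-12)
        assert res["fisher_p"] == pytest.approx(p_two, rel=1e-9)
        assert res["fisher_p"] == pytest.approx(2 / math.comb(10, 5),
                                                rel=1e-9)

    def test_all_stay_p_one(self):
        design = make_design(8)
        before = {f"S{i}_B": 1 + i % 2 for i in range(8)}
        after = {f"S{i}_A": 1 + i % 2 for i in range(8)}
        res = transition_analysis(before, after, design, focus_cluster=1)
        assert res["contingency"][:, 1].sum() == 0
        assert res["fisher_p"] == 1.0

    def test_empty_focus_cluster(self):
        design = make_design(4)
        before = {f"S{i}_B": 1 for i in range(4)}
        after = {f"S{i}_A": 1 for i in range(4)}
        with pytest.raises(ValueError):
            transition_analysis(before, after, design, focus_cluster=2)

    def test_unlabelled_subjects_dropped(self):
        design = make_design(6)
        before = {f"S{i}_B": 1 + i % 2 for i in range(5)}
        after = {f"S{i}_A": 1 for i in range(6)}
        res = transition_analysis(before, after, design, focus_cluster=1)
        assert res["n_subjects"] == 5
        assert res["n_dropped"] == 1
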