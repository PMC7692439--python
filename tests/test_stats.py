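"""ANOSIM, one-way PERMANOVA, and non-metric MDS."""
from itertools import combinations

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kstest, rankdata

from otukit import DissimilarityMatrix, anosim, nmds, permanova_oneway


def dmatrix(points, ids=None, scale=True):
    d = squareform(pdist(np.asarray(points, dtype=float)))
    if scale and d.max() > 0:
        d = d / d.max()
    ids = ids or [f"s{i}" for i in range(len(points))]
    return DissimilarityMatrix(tuple(ids), d, "bray_curtis")


def anosim_r_oracle(values, labels):
    """Clarke's R from first principles: rank-based, average ranks for ties."""
    n = values.shape[0]
    pairs = list(combinations(range(n), 2))
    dists = np.array([values[i, j] for i, j in pairs])
    ranks = rankdata(dists)
    between = np.array([labels[i] != labels[j] for i, j in pairs])
    m = len(pairs)
    return (ranks[between].mean() - ranks[~between].mean()) / (m / 2)


def two_clusters(rng, n_per=4, sep=5.0):
    a = rng.normal(0, 1, (n_per, 2))
    b = rng.normal(sep, 1, (n_per, 2))
    return np.vstack([a, b]), ["A"] * n_per + ["B"] * n_per


class TestAnosim:
    def test_perfect_separation_gives_r_of_one(self, rng):
        pts, labels = two_clusters(rng, sep=50.0)
        res = anosim(dmatrix(pts), labels, n_permutations=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p_value <= 0.05

    def test_statistic_matches_independent_rank_oracle(self, rng):
        pts = rng.normal(0, 1, (9, 3))
        labels = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        d = dmatrix(pts)
        res = anosim(d, labels, n_permutations=9, seed=0)
        assert res.r == pytest.approx(anosim_r_oracle(d.values, labels), abs=1e-12)

    def test_p_value_matches_exhaustive_enumeration(self, rng):
        # 6 samples, two groups of 3: only C(6,3)=20 label placements exist.
        pts, labels = two_clusters(rng, n_per=3, sep=2.0)
        d = dmatrix(pts)
        r_obs = anosim_r_oracle(d.values, labels)
        stats = []
        for pos in combinations(range(6), 3):
            lab = ["B"] * 6
            for i in pos:
                lab[i] = "A"
            stats.append(anosim_r_oracle(d.values, lab))
        p_exact = np.mean([s >= r_obs - 1e-12 for s in stats])
        res = anosim(d, labels, n_permutations=9999, seed=1)
        assert res.p_value == pytest.approx(p_exact, abs=0.02)

    def test_null_relabelings_average_to_zero(self, rng):
        pts = rng.normal(0, 1, (8, 2))
        d = dmatrix(pts)
        rs = []
        for _ in range(300):
            labels = rng.permutation(["A"] * 4 + ["B"] * 4).tolist()
            rs.append(anosim_r_oracle(d.values, labels))
        rs = np.array(rs)
        se = rs.std(ddof=1) / np.sqrt(len(rs))
        assert abs(rs.mean()) < 3 * se + 1e-3

    def test_invariant_under_monotone_transform_of_distances(self, rng):
        pts, labels = two_clusters(rng, sep=2.0)
        d = dmatrix(pts)
        transformed = DissimilarityMatrix(d.sample_ids, np.sqrt(d.values), "bray_curtis")
        r1 = anosim(d, labels, n_permutations=9, seed=0).r
        r2 = anosim(transformed, labels, n_permutations=9, seed=0).r
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_rejects_singleton_group_and_constant_matrix(self, rng):
        pts = rng.normal(0, 1, (5, 2))
        with pytest.raises(ValueError, match="at least 2 samples"):
            anosim(dmatrix(pts), ["A", "A", "A", "A", "B"])
        const = DissimilarityMatrix(
            ("a", "b", "c", "d"), np.ones((4, 4)) - np.eye(4), "jaccard")
        with pytest.raises(ValueError, match="constant"):
            anosim(const, ["A", "A", "B", "B"])


def gower_ss_oracle(values, labels):
    """SS via Gower centering: G = -0.5 J D^2 J; SS_total = tr(G)/..."""
    d2 = values ** 2
    n = values.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ d2 @ j
    ss_total = np.trace(g)
    ss_within = 0.0
    arr = np.asarray(labels)
    for lab in np.unique(arr):
        idx = np.flatnonzero(arr == lab)
        sub = values[np.ix_(idx, idx)] ** 2
        m = len(idx)
        jg = np.eye(m) - np.ones((m, m)) / m
        ss_within += np.trace(-0.5 * jg @ sub @ jg)
    return ss_total, ss_within


class TestPermanova:
    def test_ss_decomposition_matches_gower_oracle(self, rng):
        pts = rng.normal(0, 1, (5, 2))
        labels = ["A", "A", "B", "B", "B"]
        d = dmatrix(pts)
        res = permanova_oneway(d, labels, n_permutations=9, seed=0)
        ss_total, ss_within = gower_ss_oracle(d.values, labels)
        assert res.ss_total == pytest.approx(ss_total, abs=1e-10)
        assert res.ss_within == pytest.approx(ss_within, abs=1e-10)
        f_oracle = ((ss_total - ss_within) / 1) / (ss_within / 3)
        assert res.pseudo_f == pytest.approx(f_oracle, rel=1e-9)
        assert (res.df_between, res.df_within) == (1, 3)

    def test_duplicated_points_within_groups_flagged_infinite_f(self):
        pts = [[0, 0], [0, 0], [3, 0], [3, 0]]
        res = permanova_oneway(dmatrix(pts), ["A", "A", "B", "B"],
                               n_permutations=99, seed=0)
        assert res.infinite_f
        assert np.isinf(res.pseudo_f)
        assert 0 < res.p_value <= 1

    def test_pseudo_f_invariant_to_relabeling_within_groups(self, rng):
        pts, labels = two_clusters(rng, sep=2.0)
        d = dmatrix(pts)
        f1 = permanova_oneway(d, labels, n_permutations=9, seed=0).pseudo_f
        swapped = list(labels)
        swapped[0], swapped[1] = swapped[1], swapped[0]  # same partition
        f2 = permanova_oneway(d, swapped, n_permutations=9, seed=0).pseudo_f
        assert f1 == pytest.approx(f2, rel=1e-12)

    def test_same_seed_is_bit_reproducible(self, rng):
        pts, labels = two_clusters(rng, sep=1.0)
        d = dmatrix(pts)
        r1 = permanova_oneway(d, labels, n_permutations=199, seed=5)
        r2 = permanova_oneway(d, labels, n_permutations=199, seed=5)
        assert (r1.pseudo_f, r1.p_value) == (r2.pseudo_f, r2.p_value)

    def test_null_p_values_approximately_uniform(self, rng):
        pvals = []
        for _ in range(150):
            pts = rng.normal(0, 1, (10, 2))
            labels = ["A"] * 5 + ["B"] * 5
            pvals.append(permanova_oneway(dmatrix(pts), labels,
                                          n_permutations=99, seed=7).p_value)
        assert kstest(pvals, "uniform").pvalue > 1e-3


class TestNmds:
    def test_equilateral_triangle_embeds_with_near_zero_stress(self):
        d = DissimilarityMatrix(("a", "b", "c"),
                                0.5 * (np.ones((3, 3)) - np.eye(3)), "jaccard")
        res = nmds(d, n_restarts=4, seed=0)
        assert res.stress == pytest.approx(0.0, abs=1e-3)

    def test_planar_square_embeds_with_low_stress(self):
        pts = [[0, 0], [1, 0], [1, 1], [0, 1]]
        res = nmds(dmatrix(pts), n_restarts=8, seed=0)
        assert res.stress < 0.01
        assert res.coordinates.shape == (4, 2)

    def test_stress_depends_only_on_dissimilarity_ranks(self, rng):
        pts = rng.normal(0, 1, (8, 3))
        d = dmatrix(pts)
        monotone = DissimilarityMatrix(d.sample_ids, d.values ** 1.7, d.metric)
        s1 = nmds(d, n_restarts=6, seed=3).stress
        s2 = nmds(monotone, n_restarts=6, seed=3).stress
        assert s1 == pytest.approx(s2, abs=0.02)

    def test_reported_stress_is_best_of_restarts(self, rng):
        pts = rng.normal(0, 1, (7, 4))
        d = dmatrix(pts)
        many = nmds(d, n_restarts=10, seed=0).stress
        one = nmds(d, n_restarts=1, seed=0).stress
        assert many <= one + 1e-12

    def test_too_few_samples_rejected(self):
        d = DissimilarityMatrix(("a", "b"), np.array([[0, 1.0], [1.0, 0]]), "jaccard")
        with pytest.raises(ValueError):
            nmds(d)
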