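from itertools import permutations

import numpy as np
import pandas as pd
import pytest

import morphspec as ms
from morphspec.group_stats import boot_results_frame
from morphspec.rnl import QuantumCatchTable


def euclidean_matrix(points):
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))


def manova_f_oracle(X, labels):
    """Brute-force one-way decomposition in coordinate space.

    Independent of the distance-based route: sums squared deviations from
    grand and group means directly.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    labels = np.asarray(labels)
    grand = X.mean(axis=0)
    ss_total = ((X - grand) ** 2).sum()
    ss_within = sum(((X[labels == g] - X[labels == g].mean(axis=0)) ** 2).sum()
                    for g in np.unique(labels))
    a, n = len(np.unique(labels)), len(labels)
    ss_between = ss_total - ss_within
    F = (ss_between / (a - 1)) / (ss_within / (n - a))
    return F, ss_total, ss_within, ss_between


def enumeration_p_oracle(D, labels):
    """Exhaustive permutation p computed from scratch (all label orders)."""
    labels = np.asarray(labels)
    n = len(labels)

    def pseudo_f(lab):
        D2 = D ** 2
        ss_total = D2[np.triu_indices(n, 1)].sum() / n
        ss_within = 0.0
        for g in np.unique(lab):
            idx = np.flatnonzero(lab == g)
            ss_within += D2[np.ix_(idx, idx)][np.triu_indices(len(idx), 1)].sum() / len(idx)
        a = len(np.unique(lab))
        return ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))

    f_obs = pseudo_f(labels)
    seen, stats = set(), []
    for perm in permutations(range(n)):
        key = tuple(labels[list(perm)])
        if key not in seen:
            seen.add(key)
            stats.append(pseudo_f(np.asarray(key)))
    return float(np.mean(np.asarray(stats) >= f_obs - 1e-12))


class TestPermanova:
    points = np.array([0.0, 0.1, 1.0, 1.1])
    labels = np.array(["a", "a", "b", "b"])

    def test_worked_four_point_example(self):
        # oracle first: coordinate-space brute force
        F_oracle, sst, ssw, ssb = manova_f_oracle(self.points, self.labels)
        assert F_oracle == pytest.approx(200.0, rel=1e-10)
        assert sst == pytest.approx(1.01)
        res = ms.permanova(euclidean_matrix(self.points), self.labels,
                           method="exact")
        assert res.F == pytest.approx(200.0, rel=1e-9)
        assert res.ss_total == pytest.approx(1.01, rel=1e-10)
        assert res.ss_within == pytest.approx(0.01, rel=1e-10)
        assert res.R2 == pytest.approx(1.0 / 1.01, rel=1e-9)
        assert res.df == 1

    def test_exact_p_equals_enumeration_oracle(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=7)
        pts[4:] += 1.5
        labels = np.array(["a"] * 4 + ["b"] * 3)
        D = euclidean_matrix(pts)
        res = ms.permanova(D, labels, method="exact")
        assert res.p == pytest.approx(enumeration_p_oracle(D, labels), abs=1e-12)

    def test_permutation_p_converges_to_exact(self):
        rng = np.random.default_rng(12)
        pts = np.concatenate([rng.normal(size=4), rng.normal(2.0, size=4)])
        labels = np.array(["a"] * 4 + ["b"] * 4)
        D = euclidean_matrix(pts)
        exact = ms.permanova(D, labels, method="exact").p
        mc = ms.permanova(D, labels, n_perm=4999, seed=1).p
        assert mc == pytest.approx(exact, abs=0.05)

    def test_ss_matches_coordinate_space(self):
        rng = np.random.default_rng(23)
        X = rng.normal(size=(12, 3))
        labels = np.repeat(["a", "b", "c"], 4)
        F_o, sst_o, ssw_o, ssb_o = manova_f_oracle(X, labels)
        res = ms.permanova(euclidean_matrix(X), labels, n_perm=9, seed=0)
        assert res.ss_total == pytest.approx(sst_o, abs=1e-9)
        assert res.ss_within == pytest.approx(ssw_o, abs=1e-9)
        assert res.ss == pytest.approx(ssb_o, abs=1e-9)
        assert res.F == pytest.approx(F_o, rel=1e-9)

    def test_null_configuration_large_p(self):
        # mirror-symmetric configuration relabelled into identical multisets
        pts = np.array([0.0, 1.0, 2.0, 3.0])
        labels = np.array(["a", "b", "b", "a"])
        res = ms.permanova(euclidean_matrix(pts), labels, n_perm=999, seed=3)
        assert res.R2 < 0.05
        assert res.p > 0.5

    def test_invariant_to_relabeling_and_row_permutation(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(10, 2))
        pts[5:] += 1.0
        labels = np.repeat(["a", "b"], 5)
        D = euclidean_matrix(pts)
        base = ms.permanova(D, labels, n_perm=9, seed=0)
        swapped = ms.permanova(D, np.where(labels == "a", "x", "w"),
                               n_perm=9, seed=0)
        order = rng.permutation(10)
        reordered = ms.permanova(D[np.ix_(order, order)], labels[order],
                                 n_perm=9, seed=0)
        for other in (swapped, reordered):
            assert other.F == pytest.approx(base.F, rel=1e-12)
            assert other.R2 == pytest.approx(base.R2, rel=1e-12)

    def test_invariant_to_distance_scaling(self):
        rng = np.random.default_rng(31)
        pts = rng.normal(size=(9, 2))
        labels = np.repeat(["a", "b", "c"], 3)
        D = euclidean_matrix(pts)
        r1 = ms.permanova(D, labels, n_perm=99, seed=5)
        r2 = ms.permanova(7.3 * D, labels, n_perm=99, seed=5)
        assert r2.F == pytest.approx(r1.F, rel=1e-12)
        assert r2.R2 == pytest.approx(r1.R2, rel=1e-12)
        assert r2.p == r1.p

    def test_degenerate_within_zero(self):
        pts = np.array([0.0, 0.0, 1.0, 1.0])
        labels = np.array(["a", "a", "b", "b"])
        res = ms.permanova(euclidean_matrix(pts), labels, n_perm=99, seed=0)
        assert np.isinf(res.F)
        assert 0 < res.p <= 1


class TestPairwisePermanova:
    def make(self):
        rng = np.random.default_rng(14)
        X = np.concatenate([rng.normal(0, 1, (5, 2)), rng.normal(3, 1, (5, 2)),
                            rng.normal(6, 1, (5, 2))])
        labels = np.repeat(["orange", "white", "yellow"], 5)
        return euclidean_matrix(X), labels

    def test_three_groups_three_comparisons(self):
        D, labels = self.make()
        res = ms.pairwise_permanova(D, labels, n_perm=99, seed=0)
        assert [r.comparison for r in res] == [
            "orange-white", "orange-yellow", "white-yellow"]
        for r in res:
            assert r.p_adjusted == pytest.approx(min(1.0, r.p * 3))

    def test_adjust_none(self):
        D, labels = self.make()
        res = ms.pairwise_permanova(D, labels, adjust="none", n_perm=99, seed=0)
        for r in res:
            assert r.p_adjusted == r.p

    def test_two_groups_multiplier_one(self):
        D, labels = self.make()
        mask = labels != "yellow"
        res = ms.pairwise_permanova(D[np.ix_(mask, mask)], labels[mask],
                                    n_perm=99, seed=0)
        assert len(res) == 1
        assert res[0].p_adjusted == res[0].p


class TestDispersion:
    def test_mirror_groups_equal_dispersion(self):
        X = np.array([[0.0, 0], [1, 0], [0, 1],
                      [10.0, 0], [11, 0], [10, 1]])
        labels = np.repeat(["a", "b"], 3)
        res = ms.dispersion_test(euclidean_matrix(X), labels, n_perm=99, seed=0)
        assert res.F == pytest.approx(0.0, abs=1e-9)

    def test_unequal_dispersion_detected(self):
        rng = np.random.default_rng(20)
        X = np.concatenate([rng.normal(0, 0.1, (20, 2)),
                            rng.normal(0, 3.0, (20, 2))])
        labels = np.repeat(["tight", "wide"], 20)
        res = ms.dispersion_test(euclidean_matrix(X), labels, n_perm=199, seed=0)
        assert res.F > 10
        assert res.p < 0.05

    def test_equal_within_distances_give_zero_f(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        labels = np.array(["a", "a", "b", "b"])
        res = ms.dispersion_test(euclidean_matrix(X), labels, n_perm=19, seed=0)
        assert res.F == 0.0

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            ms.dispersion_test(np.zeros((4, 4)), ["a", "a", "b", "b"])


def table_from_logcatches(f, fa, groups):
    Q = np.exp(np.asarray(f, dtype=float))
    Qa = np.exp(np.asarray(fa, dtype=float))
    ids = tuple(f"i{k}" for k in range(len(Q)))
    meta = pd.DataFrame({"individual_id": ids, "morph": groups,
                         "sex": ["M"] * len(ids)})
    t = QuantumCatchTable(ids=ids, channels=("u", "s", "m", "l"), Q=Q,
                          Q_achro=Qa, visual_system="t", illuminant="t")
    return t, meta


class TestBootstrapDistances:
    def test_degenerate_zero_variance(self, lizard):
        fa = np.array([[0.1, 0.2, 0.3, 0.4]] * 3)
        fb = np.array([[0.5, 0.2, 0.1, 0.4]] * 3)
        t, meta = table_from_logcatches(
            np.vstack([fa, fb]), np.zeros(6),
            ["orange"] * 3 + ["white"] * 3)
        res = ms.boot_group_distance(t, meta, lizard, B=200, seed=0)
        chrom = next(r for r in res if r.channel == "chromatic")
        expect = ms.chromatic_distance(np.exp(fa[0]), np.exp(fb[0]), lizard)
        assert chrom.point == pytest.approx(expect, rel=1e-10)
        assert chrom.ci_low == pytest.approx(chrom.ci_high, abs=1e-12)
        assert chrom.ci_low == pytest.approx(chrom.point, rel=1e-10)

    def test_identical_groups_zero_point(self, lizard):
        f = np.array([[0.1, 0.2, 0.3, 0.4]] * 4)
        t, meta = table_from_logcatches(f, np.zeros(4),
                                        ["orange"] * 2 + ["white"] * 2)
        res = ms.boot_group_distance(t, meta, lizard, B=100, seed=1)
        for r in res:
            assert r.point == pytest.approx(0.0, abs=1e-12)
            assert r.ci_low == pytest.approx(0.0, abs=1e-12)

    def test_ci_width_shrinks_with_group_size(self, lizard):
        rng = np.random.default_rng(42)
        widths = []
        for n in (5, 20, 80):
            f = np.vstack([rng.normal(0.0, 0.2, size=(n, 4)),
                           rng.normal(0.6, 0.2, size=(n, 4))])
            t, meta = table_from_logcatches(f, np.zeros(2 * n),
                                            ["orange"] * n + ["white"] * n)
            res = ms.boot_group_distance(t, meta, lizard, B=400, seed=9)
            chrom = next(r for r in res if r.channel == "chromatic")
            widths.append(chrom.ci_high - chrom.ci_low)
        assert widths[0] > widths[1] > widths[2]

    def test_small_group_rejected(self, lizard):
        f = np.zeros((3, 4))
        t, meta = table_from_logcatches(f, np.zeros(3),
                                        ["orange", "orange", "white"])
        with pytest.raises(ValueError, match="fewer than 2"):
            ms.boot_group_distance(t, meta, lizard, B=10, seed=0)

    def test_unknown_pair_rejected(self, lizard):
        f = np.zeros((4, 4))
        t, meta = table_from_logcatches(f, np.zeros(4),
                                        ["orange"] * 2 + ["white"] * 2)
        with pytest.raises(ValueError, match="unknown pair"):
            ms.boot_group_distance(t, meta, lizard, pairs=[("orange", "blue")],
                                   B=10, seed=0)

    def test_results_frame_columns(self, lizard):
        f = np.vstack([np.zeros((2, 4)), np.full((2, 4), 0.3)])
        t, meta = table_from_logcatches(f, np.zeros(4),
                                        ["orange"] * 2 + ["white"] * 2)
        df = boot_results_frame(ms.boot_group_distance(t, meta, lizard,
                                                       B=50, seed=2))
        assert {"pair", "channel", "point", "ci_low", "ci_high",
                "B", "seed"} <= set(df.columns)
        assert (df["ci_low"] <= df["ci_high"]).all()
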