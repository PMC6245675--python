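"""Dissimilarity statistics: Bray-Curtis, PERMANOVA, dispersion, SIMPER, NMDS.

Independent oracles: hand evaluation of the sums of squares, brute-force
enumeration over all label permutations, a univariate ANOVA on absolute
deviations for the dispersion test, explicit pair loops for SIMPER, and
scikit-bio's implementations for cross-checking the test statistics.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist, squareform
from scipy import stats

from diasal.community import (DistanceMatrix, bray_curtis, dispersion_test,
                              env_screen, kruskal_stress, nmds, permanova,
                              simper)
from diasal.datasets import CommunityTable, EnvironmentTable


def _ct(values, unit="sqrt_percent", columns=None):
    values = np.asarray(values, dtype=float)
    columns = columns or [f"t{j}" for j in range(values.shape[1])]
    data = pd.DataFrame(values, columns=columns,
                        index=[f"S{i}" for i in range(values.shape[0])])
    return CommunityTable(data, unit=unit)


class TestBrayCurtis:
    @pytest.mark.parametrize("rows,expected", [
        ([[1.0, 2.0], [1.0, 2.0]], 0.0),          # identical rows
        ([[1.0, 0.0], [0.0, 2.0]], 1.0),          # disjoint taxa
        ([[1.0, 1.0], [0.0, 2.0]], 0.5),          # (1+1)/(1+1+0+2)
    ])
    def test_hand_values(self, rows, expected):
        d = bray_curtis(_ct(rows))
        assert d.values[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_unit_guard(self):
        ct = _ct([[1.0, 2.0], [2.0, 1.0]], unit="counts")
        with pytest.raises(ValueError, match="sqrt_percent"):
            bray_curtis(ct)
        assert bray_curtis(ct, allow_any_unit=True).values.shape == (2, 2)

    def test_two_empty_sites_rejected(self):
        ct = _ct([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="all-zero"):
            bray_curtis(ct)

    def test_matches_scipy_on_random_table(self):
        rng = np.random.default_rng(5)
        y = rng.gamma(1.0, 1.0, size=(10, 6))
        d = bray_curtis(_ct(y))
        np.testing.assert_allclose(d.condensed(), pdist(y, "braycurtis"),
                                   atol=1e-12)


def _hand_permanova_f(d, labels):
    """Independent pseudo-F: explicit double loops over site pairs."""
    d = np.asarray(d, dtype=float)
    n = len(labels)
    groups = sorted(set(labels))
    ss_total = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        ss_within += sum(d[i, j] ** 2 for i in idx for j in idx if i < j) / len(idx)
    a = len(groups)
    if ss_within == 0:
        return np.inf
    return ((ss_total - ss_within) / (a - 1)) / (ss_within / (n - a))


class TestPermanova:
    def test_degenerate_within_zero_distances(self):
        # two groups of two; within-pair distances 0, all between distances d
        d_val = 0.7
        d = np.array([[0, 0, d_val, d_val],
                      [0, 0, d_val, d_val],
                      [d_val, d_val, 0, 0],
                      [d_val, d_val, 0, 0]], dtype=float)
        dm = DistanceMatrix(list("abcd"), d)
        res = permanova(dm, ["g1", "g1", "g2", "g2"], n_permutations=99, seed=0)
        assert res.ss_total == pytest.approx(d_val ** 2)
        assert res.ss_within == pytest.approx(0.0)
        assert np.isinf(res.pseudo_F)

    def test_exhaustive_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(2)
        y = rng.gamma(1.0, 1.0, size=(4, 5))
        d = squareform(pdist(y, "braycurtis"), checks=False)
        dm = DistanceMatrix(list("abcd"), d)
        labels = ["g1", "g1", "g2", "g2"]
        res = permanova(dm, labels, exhaustive=True)
        f_obs = _hand_permanova_f(d, labels)
        count = total = 0
        for perm in itertools.permutations(range(4)):
            f = _hand_permanova_f(d, [labels[i] for i in perm])
            count += f >= f_obs - 1e-12
            total += 1
        assert res.pseudo_F == pytest.approx(f_obs, abs=1e-12)
        assert res.p_value == pytest.approx(count / total, abs=1e-12)

    def test_statistic_matches_skbio(self):
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(7)
        y = rng.gamma(1.0, 1.0, size=(12, 8))
        d = squareform(pdist(y, "braycurtis"), checks=False)
        ids = [f"S{i}" for i in range(12)]
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        mine = permanova(DistanceMatrix(ids, d), labels, n_permutations=9, seed=0)
        theirs = skbio_stats.permanova(skbio_stats.DistanceMatrix(d, ids),
                                       grouping=labels, permutations=9)
        assert mine.pseudo_F == pytest.approx(theirs["test statistic"], abs=1e-10)

    def test_seed_reproducibility_and_p_floor(self):
        rng = np.random.default_rng(11)
        y = rng.gamma(1.0, 1.0, size=(9, 5))
        d = squareform(pdist(y, "braycurtis"), checks=False)
        dm = DistanceMatrix([f"S{i}" for i in range(9)], d)
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        r1 = permanova(dm, labels, n_permutations=199, seed=42)
        r2 = permanova(dm, labels, n_permutations=199, seed=42)
        assert r1.p_value == r2.p_value
        assert r1.p_value >= 1.0 / 200

    def test_pairwise_bonferroni(self):
        rng = np.random.default_rng(13)
        y = rng.gamma(1.0, 1.0, size=(12, 6))
        d = squareform(pdist(y, "braycurtis"), checks=False)
        dm = DistanceMatrix([f"S{i}" for i in range(12)], d)
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        res = permanova(dm, labels, n_permutations=99, seed=1, pairwise=True)
        assert len(res.pairwise) == 3
        np.testing.assert_allclose(
            res.pairwise["p_bonferroni"],
            np.minimum(1.0, res.pairwise["p_raw"] * 3))

    def test_singleton_group_rejected(self):
        d = squareform(pdist(np.arange(5.0)[:, None]), checks=False)
        dm = DistanceMatrix(list("abcde"), d)
        with pytest.raises(ValueError, match="fewer than two"):
            permanova(dm, ["g1", "g1", "g1", "g1", "g2"])


class TestDispersion:
    def test_univariate_oracle(self):
        # 1-D Euclidean data: distance to centroid must equal |x - group mean|
        x = np.array([0.0, 1.0, 4.0, 10.0, 12.0, 17.0, 2.0, 3.0])
        labels = ["a", "a", "a", "b", "b", "b", "a", "b"]
        d = squareform(pdist(x[:, None]), checks=False)
        dm = DistanceMatrix([f"S{i}" for i in range(8)], d)
        res = dispersion_test(dm, labels, n_permutations=49, seed=0)
        expected = np.empty_like(x)
        for g in ("a", "b"):
            idx = [i for i, l in enumerate(labels) if l == g]
            expected[idx] = np.abs(x[idx] - x[idx].mean())
        np.testing.assert_allclose(res.distances_to_centroid.to_numpy(),
                                   expected, atol=1e-8)
        f_oracle = stats.f_oneway(expected[:4][np.array([0, 1, 2])],
                                  expected[np.array([3, 4, 5, 7])])
        grouped = [[expected[i] for i, l in enumerate(labels) if l == g]
                   for g in ("a", "b")]
        f_oracle = stats.f_oneway(*grouped).statistic
        assert res.F == pytest.approx(f_oracle, abs=1e-8)

    def test_mirror_groups_have_equal_dispersion(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(6, 2))
        cloud = np.vstack([pts, -pts + 10.0])   # second group is a mirror image
        d = squareform(pdist(cloud), checks=False)
        dm = DistanceMatrix([f"S{i}" for i in range(12)], d)
        labels = ["a"] * 6 + ["b"] * 6
        res = dispersion_test(dm, labels, n_permutations=199, seed=5)
        assert res.group_means["a"] == pytest.approx(res.group_means["b"], abs=1e-8)
        assert res.p_value > 0.5

    def test_detects_scale_difference(self):
        rng = np.random.default_rng(8)
        tight = rng.normal(scale=0.1, size=(10, 3))
        spread = rng.normal(scale=1.0, size=(10, 3))
        d = squareform(pdist(np.vstack([tight, spread])), checks=False)
        dm = DistanceMatrix([f"S{i}" for i in range(20)], d)
        res = dispersion_test(dm, ["a"] * 10 + ["b"] * 10,
                              n_permutations=999, seed=1)
        assert res.p_value < 0.05

    def test_matches_skbio_permdisp_statistic(self):
        # Euclidean distances: no negative principal-coordinate eigenvalues,
        # so the negative-axis correction is inactive and the F statistic
        # must agree with scikit-bio's permdisp
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(21)
        y = rng.gamma(1.0, 1.0, size=(12, 7))
        d = squareform(pdist(y), checks=False)
        ids = [f"S{i}" for i in range(12)]
        labels = ["a"] * 6 + ["b"] * 6
        mine = dispersion_test(DistanceMatrix(ids, d), labels,
                               n_permutations=9, seed=0)
        theirs = skbio_stats.permdisp(skbio_stats.DistanceMatrix(d, ids),
                                      grouping=labels, permutations=9,
                                      test="centroid")
        assert mine.F == pytest.approx(theirs["test statistic"], rel=1e-6)


class TestSimper:
    def test_single_pair_conservation(self):
        ct = _ct([[3.0, 1.0, 0.0], [1.0, 2.0, 2.0]])
        table = simper(ct, ["a", "b"])
        d = bray_curtis(ct).values[0, 1]
        assert table["average_dissimilarity"].sum() == pytest.approx(d, abs=1e-12)
        assert table["contribution_pct"].sum() == pytest.approx(100.0, abs=1e-8)

    def test_equal_differences_split_evenly(self):
        ct = _ct([[2.0, 0.0], [0.0, 2.0]])
        table = simper(ct, ["a", "b"])
        np.testing.assert_allclose(table["contribution_pct"], [50.0, 50.0])

    def test_brute_force_oracle_three_groups(self):
        rng = np.random.default_rng(4)
        y = rng.gamma(1.0, 1.0, size=(6, 4))
        labels = ["a", "a", "b", "b", "c", "c"]
        table = simper(_ct(y), labels).set_index("taxon")
        # explicit pooled loop over all between-group pairs
        contrib = np.zeros(4)
        n_pairs = 0
        for i in range(6):
            for j in range(i + 1, 6):
                if labels[i] == labels[j]:
                    continue
                denom = (y[i] + y[j]).sum()
                contrib += np.abs(y[i] - y[j]) / denom
                n_pairs += 1
        contrib /= n_pairs
        for k in range(4):
            assert table.loc[f"t{k}", "average_dissimilarity"] == \
                pytest.approx(contrib[k], abs=1e-12)

    def test_cumulative_nondecreasing(self):
        rng = np.random.default_rng(9)
        table = simper(_ct(rng.gamma(1.0, 1.0, size=(8, 5))),
                       ["a"] * 4 + ["b"] * 4)
        assert (np.diff(table["cumulative_pct"]) >= -1e-12).all()

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            simper(_ct([[1.0], [2.0]]), ["a", "a"])

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_conservation_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        m = int(rng.integers(2, 6))
        y = rng.gamma(0.7, 1.0, size=(n, m)) + 1e-6
        labels = ["a"] * (n // 2) + ["b"] * (n - n // 2)
        table = simper(_ct(y), labels)
        d = bray_curtis(_ct(y)).values
        between = [d[i, j] for i in range(n) for j in range(i + 1, n)
                   if labels[i] != labels[j]]
        assert table["average_dissimilarity"].sum() == \
            pytest.approx(np.mean(between), abs=1e-10)


class TestNMDS:
    def _euclidean_dm(self, pts):
        d = squareform(pdist(pts), checks=False)
        return DistanceMatrix([f"S{i}" for i in range(len(pts))], d)

    def test_perfect_two_dimensional_recovery(self):
        rng = np.random.default_rng(6)
        pts = rng.normal(size=(12, 2))
        res = nmds(self._euclidean_dm(pts), k=2, n_restarts=4, seed=0)
        assert res.stress < 1e-3

    def test_determinism(self):
        rng = np.random.default_rng(10)
        y = rng.gamma(1.0, 1.0, size=(10, 6))
        dm = bray_curtis(_ct(y))
        r1 = nmds(dm, k=2, n_restarts=5, seed=123)
        r2 = nmds(dm, k=2, n_restarts=5, seed=123)
        np.testing.assert_array_equal(r1.coordinates, r2.coordinates)
        assert r1.stress == r2.stress

    def test_reported_stress_matches_independent_evaluator(self):
        rng = np.random.default_rng(12)
        y = rng.gamma(1.0, 1.0, size=(10, 5))
        dm = bray_curtis(_ct(y))
        res = nmds(dm, k=2, n_restarts=5, seed=7)
        # independent evaluator: isotonic regression on the dissimilarity
        # order (ties broken by configuration distance), then stress-1
        from sklearn.isotonic import IsotonicRegression
        dvec = dm.condensed()
        dist = pdist(res.coordinates)
        order = np.lexsort((dist, dvec))
        disp = np.empty_like(dist)
        disp[order] = IsotonicRegression(increasing=True).fit_transform(
            np.arange(len(dvec)), dist[order])
        stress = np.sqrt(((dist - disp) ** 2).sum() / (dist ** 2).sum())
        assert res.stress == pytest.approx(stress, abs=1e-10)

    def test_stress_history_nonincreasing(self):
        rng = np.random.default_rng(14)
        y = rng.gamma(1.0, 1.0, size=(12, 6))
        res = nmds(bray_curtis(_ct(y)), k=2, n_restarts=3, seed=2)
        assert (np.diff(res.stress_history) <= 1e-12).all()

    def test_needs_enough_sites(self):
        dm = self._euclidean_dm(np.random.default_rng(0).normal(size=(3, 2)))
        with pytest.raises(ValueError, match="at least"):
            nmds(dm, k=2)


class TestEnvScreen:
    def _table(self, **cols):
        n = len(next(iter(cols.values())))
        return EnvironmentTable(pd.DataFrame(cols,
                                index=[f"S{i}" for i in range(n)]))

    def test_equal_group_means_give_zero_f(self):
        et = self._table(Cl=[1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                         v=[5.0, 6.0, 7.0, 5.0, 6.0, 7.0])
        out = env_screen(et, ["a", "a", "a", "b", "b", "b"], "Cl")
        assert out.loc["v", "anova_F"] == pytest.approx(0.0, abs=1e-12)

    def test_self_correlation_is_one(self):
        et = self._table(Cl=[1.0, 2.0, 3.0, 4.0], v=[0.0, 1.0, 1.0, 2.0])
        out = env_screen(et, ["a", "a", "b", "b"], "Cl")
        assert out.loc["Cl", "pearson_r"] == pytest.approx(1.0)

    def test_pearson_matches_textbook_formula(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 9.0])
        v = np.array([2.0, 1.0, 5.0, 4.0, 8.0])
        et = self._table(Cl=x, v=v)
        out = env_screen(et, ["a", "a", "a", "b", "b"], "Cl")
        r_hand = (((x - x.mean()) * (v - v.mean())).sum()
                  / np.sqrt(((x - x.mean()) ** 2).sum() * ((v - v.mean()) ** 2).sum()))
        assert out.loc["v", "pearson_r"] == pytest.approx(r_hand, abs=1e-12)

    def test_zero_variance_flagged_not_raised(self):
        et = self._table(Cl=[1.0, 2.0, 3.0, 4.0], flat=[1.0, 1.0, 1.0, 1.0])
        out = env_screen(et, ["a", "a", "b", "b"], "Cl")
        assert not out.loc["flat", "r_defined"]
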