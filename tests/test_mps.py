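import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from pcmkit.io import ExpressionMatrix, GeneModule, ModuleCatalog, standardize
from pcmkit.mps import (
    NullModel,
    PerturbationMatrix,
    _null_mis,
    cohort_specific_modules,
    mps,
    mutual_information,
    null_model,
    quantize_sample,
    score_cohort,
    tissue_specific_modules,
)


def brute_force_mi(table) -> float:
    """Independent double-sum oracle for I(membership; bin), in nats."""
    c = np.asarray(table, dtype=float)
    n = c.sum()
    total = 0.0
    for i in range(c.shape[0]):
        for j in range(c.shape[1]):
            pij = c[i, j] / n
            if pij == 0:
                continue
            pi = c[i, :].sum() / n
            pj = c[:, j].sum() / n
            total += pij * np.log(pij / (pi * pj))
    return total


class TestQuantize:
    def test_even_split(self):
        bins = quantize_sample(np.arange(10, dtype=float), 2)
        assert (np.bincount(bins) == [5, 5]).all()

    def test_extra_element_in_lowest_bin(self):
        bins = quantize_sample(np.arange(11, dtype=float), 2)
        assert (np.bincount(bins) == [6, 5]).all()
        # lowest values land in bin 0
        assert (bins[np.argsort(np.arange(11.0))[:6]] == 0).all()

    def test_all_equal_stable_order(self):
        bins = quantize_sample(np.zeros(10), 5)
        # stable tie-break: first two genes in bin 0, next two in bin 1, ...
        np.testing.assert_array_equal(bins, np.repeat(np.arange(5), 2))

    def test_ne_exceeds_genes(self):
        with pytest.raises(ValueError):
            quantize_sample(np.arange(3, dtype=float), 5)

    @given(st.integers(0, 10_000), st.integers(2, 12), st.integers(12, 60))
    def test_bins_rank_contiguous_and_balanced(self, seed, ne, n):
        rng = np.random.default_rng(seed)
        z = rng.normal(size=n)
        bins = quantize_sample(z, ne)
        sizes = np.bincount(bins, minlength=ne)
        assert sizes.max() - sizes.min() <= 1
        # bins are monotone along the sorted order
        assert (np.diff(bins[np.argsort(z, kind="stable")]) >= 0).all()


class TestMutualInformation:
    def test_perfect_association(self):
        assert mutual_information([[2, 0], [0, 2]]) == pytest.approx(np.log(2))

    def test_independence_zero(self):
        assert mutual_information([[1, 1], [1, 1]]) == pytest.approx(0.0)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            mutual_information([[1, -1], [0, 2]])

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(12)
        for _ in range(200):
            table = rng.integers(0, 30, size=(2, 10))
            if table.sum() == 0:
                continue
            assert mutual_information(table) == pytest.approx(
                brute_force_mi(table), abs=1e-12)

    def test_invariant_under_bin_relabeling(self):
        rng = np.random.default_rng(4)
        table = rng.integers(0, 20, size=(2, 6))
        perm = rng.permutation(6)
        assert mutual_information(table) == pytest.approx(
            mutual_information(table[:, perm]), abs=1e-12)


class TestNullModel:
    def test_all_ones_membership_degenerate(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=50)
        memb = np.ones(50, dtype=bool)
        null = null_model(memb, z, Ne=5, n_rand=200, seed=1)
        assert null.sigma == 0.0
        assert null.z(mutual_information([[0] * 5, [10] * 5])) == 0.0

    def test_observed_at_null_mean_gives_zero_mps(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=100)
        memb = np.zeros(100, dtype=bool)
        memb[:20] = True
        null = null_model(memb, z, Ne=10, n_rand=500, seed=2)
        res = mps(memb, z, Ne=10, null=null)
        # observed MI of a random membership sits near the null center
        if not res.significant:
            assert res.mps == 0.0
        assert null.z(null.mu) == 0.0

    def test_hypergeometric_null_matches_explicit_permutation(self):
        """Dual route: the multivariate-hypergeometric draw equals literally
        permuting the membership vector."""
        rng = np.random.default_rng(3)
        z = rng.normal(size=120)
        bins = quantize_sample(z, 6)
        col_totals = np.bincount(bins, minlength=6)
        m = 25
        hyper = _null_mis(col_totals, m, 120, 4000, np.random.default_rng(7))
        memb = np.zeros(120, dtype=bool)
        memb[:m] = True
        explicit = []
        rng2 = np.random.default_rng(8)
        for _ in range(4000):
            perm = rng2.permutation(memb)
            c1 = np.bincount(bins[perm], minlength=6)
            explicit.append(brute_force_mi(np.vstack([col_totals - c1, c1])))
        # MI has a discrete support; round away float-representation jitter
        # (~1e-15 between the two computation routes) so KS compares the
        # draw mechanisms, not the arithmetic order
        ks = stats.ks_2samp(np.round(hyper, 12), np.round(explicit, 12))
        assert ks.pvalue > 0.001

    def test_n_rand_floor(self):
        with pytest.raises(ValueError):
            null_model(np.array([True, False] * 10), np.arange(20.0),
                       Ne=2, n_rand=50)


class TestMps:
    def test_sign_follows_pearson(self):
        rng = np.random.default_rng(5)
        z = rng.normal(size=200)
        memb = np.zeros(200, dtype=bool)
        memb[np.argsort(z)[-30:]] = True  # module occupies the top bins
        res = mps(memb, z, Ne=10, n_rand=300, seed=6)
        assert res.r > 0
        assert res.significant and res.mps > 0

    def test_negated_expression_flips_sign(self):
        rng = np.random.default_rng(6)
        z = rng.normal(size=150)
        memb = np.zeros(150, dtype=bool)
        memb[np.argsort(z)[-25:]] = True
        a = mps(memb, z, Ne=10, n_rand=300, seed=7)
        b = mps(memb, -z, Ne=10, n_rand=300, seed=7)
        assert a.mi == pytest.approx(b.mi, abs=1e-12)
        assert a.mps == pytest.approx(-b.mps, abs=1e-9)

    def test_heaviside_magnitude_is_binary(self):
        rng = np.random.default_rng(7)
        z = rng.normal(size=150)
        memb = np.zeros(150, dtype=bool)
        memb[np.argsort(z)[-25:]] = True
        res = mps(memb, z, Ne=10, n_rand=300, seed=8, magnitude="heaviside")
        assert res.mps in (-1.0, 0.0, 1.0)

    def test_tiny_module_scored_zero_with_warning(self):
        with pytest.warns(UserWarning):
            res = mps(np.array([True] + [False] * 20), np.arange(21.0),
                      Ne=3, n_rand=100, seed=0)
        assert res.mps == 0.0


class TestScoreCohort:
    def test_requires_standardized(self, small_cohort):
        with pytest.raises(ValueError, match="standardized"):
            score_cohort(small_cohort.catalog, small_cohort.expression,
                         n_rand=100)

    def test_planted_module_samples_labeled(self, small_cohort, small_scores):
        act = small_cohort.truth.activation.loc["planted_1"]
        row = small_scores.mps.loc["planted_1"]
        up = row[act.values == 1]
        dn = row[act.values == -1]
        assert (up > 0).mean() >= 0.90
        assert (dn < 0).mean() >= 0.90

    def test_labels_match_sign(self, small_scores):
        lab = small_scores.labels()
        assert (lab.to_numpy()[small_scores.mps.to_numpy() > 0] == "plus").all()
        assert (lab.to_numpy()[small_scores.mps.to_numpy() < 0] == "minus").all()

    def test_sample_permutation_equivariance(self, small_cohort):
        z = standardize(small_cohort.expression)
        P1 = score_cohort(small_cohort.catalog, z, Ne=10, n_rand=150, seed=3)
        perm = list(reversed(z.sample_ids))
        P2 = score_cohort(small_cohort.catalog, z.subset_samples(perm),
                          Ne=10, n_rand=150, seed=3)
        pd.testing.assert_frame_equal(P1.mps[perm], P2.mps)

    def test_deterministic(self, small_cohort):
        z = standardize(small_cohort.expression)
        sub = ExpressionMatrix(z.values.iloc[:, :20], True)
        a = score_cohort(small_cohort.catalog, sub, Ne=10, n_rand=150, seed=9)
        b = score_cohort(small_cohort.catalog, sub, Ne=10, n_rand=150, seed=9)
        pd.testing.assert_frame_equal(a.mps, b.mps)

    def test_bin_count_robustness(self, small_cohort):
        """The samples labeled as activated for a planted module overlap
        heavily across bin-count choices (Ne of 6, 10, 15)."""
        z = standardize(small_cohort.expression)
        plus_sets = []
        for ne in (6, 10, 15):
            P = score_cohort(small_cohort.catalog, z, Ne=ne, n_rand=150, seed=2)
            row = P.mps.loc["planted_1"]
            plus_sets.append(set(row.index[row > 0]))
        for a in plus_sets:
            for b in plus_sets:
                jacc = len(a & b) / len(a | b)
                assert jacc > 0.5

    def test_single_pair_reduces_to_mps(self, small_cohort):
        import zlib

        z = standardize(small_cohort.expression)
        sid = z.sample_ids[0]
        one = ExpressionMatrix(z.values.iloc[:, [0]], True)
        cat = ModuleCatalog([small_cohort.catalog["planted_1"]])
        P = score_cohort(cat, one, Ne=10, n_rand=200, seed=4)
        memb = pd.Index(z.gene_ids).isin(cat["planted_1"].genes)
        zcol = z.values.iloc[:, 0].to_numpy()
        # rebuild the same per-(sample, size) null substream
        child = np.random.SeedSequence(
            entropy=4, spawn_key=(zlib.crc32(sid.encode()), int(memb.sum())))
        from pcmkit.mps import _null_mis

        bins = quantize_sample(zcol, 10)
        ct = np.bincount(bins, minlength=10)
        mis = _null_mis(ct, int(memb.sum()), memb.size, 200,
                        np.random.default_rng(child))
        null = NullModel(200, float(mis.mean()), float(mis.std()),
                         float(np.quantile(mis, 0.99, method="higher")), 4)
        single = mps(memb, zcol, Ne=10, null=null)
        assert P.mps.iloc[0, 0] == pytest.approx(single.mps, abs=1e-12)


class TestSpecificityFilters:
    def _pmatrix(self, mat):
        names = [f"m{i}" for i in range(mat.shape[0])]
        cols = [f"s{j}" for j in range(mat.shape[1])]
        df = pd.DataFrame(mat, index=names, columns=cols)
        return PerturbationMatrix(df, df != 0)

    def test_constant_module_selected(self):
        mat = np.vstack([np.full(10, 2.0), np.random.default_rng(0).normal(size=10)])
        sel = cohort_specific_modules(self._pmatrix(mat), 0.5, 0.5)
        assert "m0" in sel

    def test_all_zero_never_selected(self):
        rng = np.random.default_rng(1)
        mat = np.vstack([np.zeros(10), rng.normal(size=(4, 10))])
        assert "m0" not in cohort_specific_modules(self._pmatrix(mat), 1.0, 1.0)

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(2)
        mat = rng.normal(size=(50, 30)) * (rng.random((50, 30)) < 0.5)
        P = self._pmatrix(mat)
        got = set(cohort_specific_modules(P, 0.5, 0.4))
        expected = set()
        for stream in (np.clip(mat, 0, None), np.clip(-mat, 0, None)):
            means, variances = stream.mean(axis=1), stream.var(axis=1)
            act = means > 0
            mc = np.quantile(means[act], 0.5)
            vc = np.quantile(variances[act], 0.4)
            for i in np.flatnonzero(act & (means >= mc) & (variances <= vc)):
                expected.add(f"m{i}")
        assert got == expected

    def test_quantile_validation(self):
        with pytest.raises(ValueError):
            cohort_specific_modules(self._pmatrix(np.ones((2, 3))), 0.0, 0.4)

    def test_tissue_opposite_signs_selected(self):
        t = self._pmatrix(np.full((1, 8), 1.0))
        n = self._pmatrix(np.full((1, 8), -1.0))
        assert tissue_specific_modules(t, n, 0.75) == ["m0"]

    def test_tumor_only_significant_not_selected(self):
        t = self._pmatrix(np.full((1, 8), 1.0))
        n = self._pmatrix(np.zeros((1, 8)))
        assert tissue_specific_modules(t, n, 0.75) == []

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(3)
        mt = rng.choice([-1.0, 0.0, 1.0], size=(20, 12))
        mn = rng.choice([-1.0, 0.0, 1.0], size=(20, 12))
        t, n = self._pmatrix(mt), self._pmatrix(mn)
        got = set(tissue_specific_modules(t, n, 0.5))
        expected = {f"m{i}" for i in range(20)
                    if np.mean(mt[i] * mn[i] < 0) >= 0.5}
        assert got == expected

    def test_no_pairs_raises(self):
        t = self._pmatrix(np.ones((1, 2)))
        n = PerturbationMatrix(
            pd.DataFrame(np.ones((1, 2)), index=["m0"], columns=["x", "y"]),
            pd.DataFrame(True, index=["m0"], columns=["x", "y"]))
        with pytest.raises(ValueError):
            tissue_specific_modules(t, n)
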