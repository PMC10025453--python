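import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pcmkit.discovery import (
    BoundaryConditions,
    boundary_from_arms,
    categorize_cna,
    discover_pcms,
    fisher_association_p,
    make_folds,
    merge_stage,
    partition_cohort,
    propagate_boundaries,
    rank_product_cna,
    select_mutated_genes,
    stage_association,
)
from pcmkit.io import ExpressionMatrix, GeneModule, ModuleCatalog


class TestFolds:
    def test_partition_exact_and_balanced(self):
        ids = [f"p{i}" for i in range(100)]
        folds = make_folds(ids, 3, seed=1)
        assert sorted(folds.index) == sorted(ids)
        counts = folds.value_counts()
        assert set(folds.unique()) == {1, 2, 3}
        assert counts.max() - counts.min() <= 1

    def test_event_stratification(self):
        rng = np.random.default_rng(2)
        ids = [f"p{i}" for i in range(90)]
        event = rng.random(90) < 0.3
        folds = make_folds(ids, 3, seed=3, event=event)
        per_fold_events = [event[folds.to_numpy() == f].sum() for f in (1, 2, 3)]
        assert max(per_fold_events) - min(per_fold_events) <= 1


class TestBoundaries:
    def test_least_positive_cut(self):
        train = pd.Series([0.9, 0.7, 0.5, 0.2, -0.6, -0.8, -0.9],
                          index=list("abcdefg"))
        labels = pd.Series(["plus", "plus", "plus", "none",
                            "minus", "minus", "minus"], index=list("abcdefg"))
        b = boundary_from_arms(train, labels)
        assert b.plus_cut == pytest.approx(0.5)
        assert b.minus_cut == pytest.approx(-0.6)  # least-extreme negative
        test = pd.Series([0.6, 0.4, 0.5, -0.7, -0.5, 0.0],
                         index=list("uvwxyz"))
        lab = propagate_boundaries(b, test)
        assert lab["u"] == "plus"
        assert lab["v"] == "none"
        assert lab["w"] == "plus"  # boundary is closed
        assert lab["x"] == "minus"
        assert lab["y"] == "none"
        assert lab["z"] == "none"

    def test_literal_repressed_rule(self):
        train = pd.Series([-0.5, -0.9], index=list("ab"))
        labels = pd.Series(["minus", "minus"], index=list("ab"))
        b = boundary_from_arms(train, labels, literal_repressed=True)
        assert b.minus_cut == pytest.approx(-0.9)

    def test_all_zero_test_unlabeled(self):
        b = BoundaryConditions(0.5, -0.5)
        lab = propagate_boundaries(b, pd.Series(0.0, index=list("abc")))
        assert (lab == "none").all()


class TestFisher:
    def test_extreme_table_tiny_p(self):
        table = np.array([[10, 0], [8, 0], [0, 8], [0, 10]])
        assert fisher_association_p(table, seed=0) < 1e-3

    def test_2x2_matches_hypergeometric_oracle(self):
        table = np.array([[8, 2], [3, 9]])
        p = fisher_association_p(table)
        # two-sided Fisher: sum of hypergeometric probabilities <= observed
        n1, n2 = table.sum(axis=1)
        k = table[:, 0].sum()
        probs = [stats.hypergeom.pmf(x, n1 + n2, n1, k)
                 for x in range(max(0, k - n2), min(k, n1) + 1)]
        obs = stats.hypergeom.pmf(table[0, 0], n1 + n2, n1, k)
        expected = sum(pr for pr in probs if pr <= obs * (1 + 1e-9))
        assert p == pytest.approx(expected, rel=1e-9)

    def test_monte_carlo_calibrated_on_independent_table(self):
        rng = np.random.default_rng(4)
        # a 4x2 table drawn under independence should rarely look extreme
        p = fisher_association_p(np.array([[5, 6], [7, 5], [6, 6], [5, 7]]),
                                 seed=1)
        assert p > 0.1

    def test_all_zero_stage_row_retained(self):
        table = np.array([[5, 1], [0, 0], [1, 5], [2, 2]])
        p = fisher_association_p(table, seed=2)
        assert 0 < p <= 1


class TestCnaPartitioning:
    def test_quantile_by_hand(self):
        vals = pd.Series([4.0, 3.0, 2.0, 1.0], index=list("abcd"))
        cats = categorize_cna(vals, 0.25)
        assert cats["a"] == "deep_amplified"
        assert list(cats[list("bcd")]) == ["amplified"] * 3

    def test_single_positive_is_deep(self):
        cats = categorize_cna(pd.Series([2.5], index=["a"]), 0.25)
        assert cats["a"] == "deep_amplified"

    def test_sign_flip_mirrors_categories(self):
        vals = pd.Series([4.0, 3.0, 2.0, 1.0], index=list("abcd"))
        up = categorize_cna(vals, 0.25)
        dn = categorize_cna(-vals, 0.25)
        mirror = {"deep_amplified": "deep_deleted", "amplified": "deleted"}
        assert list(dn) == [mirror[c] for c in up]

    def test_zeros_uncategorized(self):
        cats = categorize_cna(pd.Series([0.0, 1.0, -1.0], index=list("abc")), 0.25)
        assert pd.isna(cats["a"])


class TestMutationSelection:
    def _snv(self):
        samples = [f"p{i}" for i in range(100)]
        data = {
            "A": np.r_[np.ones(30), np.zeros(70)],  # 30 muts / 3000 bp
            "B": np.r_[np.ones(20), np.zeros(80)],  # 20 muts / 1000 bp
            "C": np.r_[np.ones(4), np.zeros(96)],  # below 5% prevalence
            "TTN": np.ones(100),
        }
        return pd.DataFrame(data, index=samples).T

    def test_rate_per_bp_ranking(self):
        lengths = pd.Series({"A": 3000.0, "B": 1000.0, "C": 500.0, "TTN": 1e5})
        got = select_mutated_genes(self._snv(), lengths, top_k=2)
        assert got == ["B", "A"]  # B: 0.02/bp beats A: 0.01/bp

    def test_low_prevalence_excluded(self):
        lengths = pd.Series({"A": 3000.0, "B": 1000.0, "C": 500.0, "TTN": 1e5})
        assert "C" not in select_mutated_genes(self._snv(), lengths, top_k=4)

    def test_ttn_never_returned(self):
        lengths = pd.Series({"A": 3000.0, "B": 1000.0, "C": 500.0, "TTN": 1e5})
        assert "TTN" not in select_mutated_genes(self._snv(), lengths, top_k=4)

    def test_missing_length_skipped(self):
        lengths = pd.Series({"A": 3000.0, "TTN": 1e5})
        got = select_mutated_genes(self._snv(), lengths, top_k=3)
        assert got == ["A"]


class TestRankProduct:
    def test_rank_product_by_hand(self):
        # |median| ranks [1,2,3], SD ranks [2,3,1] -> RP [2,6,3]
        rng = np.random.default_rng(5)
        n = 200
        base = rng.normal(size=(3, n))
        rows = [
            0.5 + 0.20 * (base[0] - base[0].mean()) / base[0].std(),
            1.0 + 0.30 * (base[1] - base[1].mean()) / base[1].std(),
            2.0 + 0.10 * (base[2] - base[2].mean()) / base[2].std(),
        ]
        cna = pd.DataFrame(rows, index=["g1", "g2", "g3"],
                           columns=[f"p{i}" for i in range(n)])
        got = rank_product_cna(cna, top_k=3, corr_cut=1.1)
        assert got[0] == "g2"

    def test_correlated_pair_pruned(self):
        rng = np.random.default_rng(6)
        n = 100
        a = rng.normal(2, 1, n)
        cna = pd.DataFrame(
            [a, a * 1.01, rng.normal(0, 0.1, n)],
            index=["g1", "g2", "g3"], columns=[f"p{i}" for i in range(n)])
        got = rank_product_cna(cna, top_k=3, corr_cut=0.5)
        assert not ({"g1", "g2"} <= set(got))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(7)
        cna = pd.DataFrame(rng.normal(1, 1, (10, 50)),
                           index=[f"g{i}" for i in range(10)],
                           columns=[f"p{i}" for i in range(50)])
        med = np.abs(np.median(cna, axis=1))
        sd = cna.std(axis=1, ddof=1)
        rp = stats.rankdata(med) * stats.rankdata(sd)
        rp2 = stats.rankdata(np.exp(med)) * stats.rankdata(sd**3)
        np.testing.assert_array_equal(rp, rp2)


class TestPartitionCohort:
    def _clinical(self):
        rng = np.random.default_rng(8)
        n = 120
        return pd.DataFrame({
            "stage": rng.choice(["I", "IA", "IIB", "IIIC", "IV"], n),
            "age": rng.uniform(20, 80, n),
            "sex": rng.choice(["female", "male"], n),
        }, index=[f"p{i}" for i in range(n)])

    def test_stage_merging(self):
        assert merge_stage("Stage IA") == "I"
        assert merge_stage("IIB") == "II"
        assert merge_stage("IIIC") == "III"
        assert merge_stage("IVA") == "IV"

    def test_age_buckets_and_min_size(self):
        specs = partition_cohort(self._clinical(), min_size=21)
        names = {s.name for s in specs}
        assert any(n.startswith("age=") for n in names)
        assert all(len(s) >= 21 for s in specs)

    def test_stage_subgroups_merged(self):
        specs = partition_cohort(self._clinical(), attributes=["stage"],
                                 min_size=5)
        values = {s.value for s in specs}
        assert values <= {"I", "II", "III", "IV"}

    def test_unknown_attribute_raises(self):
        with pytest.raises(ValueError, match="unknown"):
            partition_cohort(self._clinical(), attributes=["histology"])


class TestDiscovery:
    def test_cv_hygiene_exact_partition(self, small_cohort):
        decs, details = discover_pcms(
            small_cohort.expression, small_cohort.catalog,
            small_cohort.outcomes, schedule=[15], Ne=10, n_rand=100,
            n_null=100, seed=3, return_details=True)
        test_ids = sorted(
            sid for f in details.test_scores
            for sid in details.test_scores[f].sample_ids)
        assert test_ids == sorted(small_cohort.expression.sample_ids)

    def test_training_scores_blind_to_test_values(self, small_cohort):
        x = small_cohort.expression
        _, det1 = discover_pcms(x, small_cohort.catalog, small_cohort.outcomes,
                                schedule=[15], Ne=10, n_rand=100, n_null=100,
                                seed=4, return_details=True)
        fold = det1.folds
        vals = x.values.copy()
        test_ids = fold.index[fold == 1]
        vals.loc[:, test_ids] += np.random.default_rng(0).normal(
            0, 5, (vals.shape[0], len(test_ids)))
        x2 = ExpressionMatrix(vals)
        _, det2 = discover_pcms(x2, small_cohort.catalog, small_cohort.outcomes,
                                schedule=[15], Ne=10, n_rand=100, n_null=100,
                                seed=4, return_details=True)
        pd.testing.assert_frame_equal(det1.train_scores[1].mps,
                                      det2.train_scores[1].mps)

    def test_planted_module_recovered_decoys_not(self, small_cohort):
        decs = discover_pcms(small_cohort.expression, small_cohort.catalog,
                             small_cohort.outcomes, schedule=[15, 20],
                             Ne=10, n_rand=200, n_null=300, seed=5)
        by_mod = {}
        for d in decs:
            by_mod[d.module] = by_mod.get(d.module, False) or d.is_pcm
        assert by_mod.get("planted_1", False)
        decoy_passes = sum(v for m, v in by_mod.items() if m.startswith("decoy"))
        assert decoy_passes == 0

    def test_relaxed_thresholds_grow_pcm_set_monotonically(self, small_cohort):
        from pcmkit.discovery import SUBCOHORT_THRESHOLDS, PcmThresholds, apply_thresholds

        decs = discover_pcms(small_cohort.expression, small_cohort.catalog,
                             small_cohort.outcomes, schedule=[15, 20],
                             Ne=10, n_rand=150, n_null=200, seed=12)
        strict = apply_thresholds(decs, PcmThresholds())
        relaxed = apply_thresholds(decs, SUBCOHORT_THRESHOLDS)
        assert strict <= relaxed
        # default decisions agree with the default thresholds
        assert strict == {d.module for d in decs if d.is_pcm}

    def test_deterministic_given_seed(self, small_cohort):
        kw = dict(schedule=[15], Ne=10, n_rand=100, n_null=100, seed=6)
        a = discover_pcms(small_cohort.expression, small_cohort.catalog,
                          small_cohort.outcomes, **kw)
        b = discover_pcms(small_cohort.expression, small_cohort.catalog,
                          small_cohort.outcomes, **kw)
        assert [(d.module, d.group_size, d.is_pcm, d.test_fdr) for d in a] == \
               [(d.module, d.group_size, d.is_pcm, d.test_fdr) for d in b]


class TestStageAssociation:
    def test_stage_linked_module_flagged(self):
        rng = np.random.default_rng(9)
        n, g = 150, 300
        genes = [f"g{i}" for i in range(g)]
        samples = [f"s{i}" for i in range(n)]
        vals = rng.normal(size=(g, n))
        # module genes shift up in advanced-stage samples, down in early
        stage = np.where(np.arange(n) < 75, "I", "IV")
        vals[:40, stage == "IV"] += 2.5
        vals[:40, stage == "I"] -= 2.5
        x = ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=samples))
        cat = ModuleCatalog([
            GeneModule("linked", frozenset(genes[:40])),
            GeneModule("decoy", frozenset(rng.choice(genes, 40, replace=False))),
        ])
        stages = pd.Series(stage, index=samples)
        decs = stage_association(x, cat, stages, schedule=[20],
                                 Ne=10, n_rand=200, seed=10)
        flags = {d.module: d.is_associated for d in decs}
        assert flags.get("linked", False)
        assert not flags.get("decoy", False)

    def test_requires_two_stages(self, small_cohort):
        stages = pd.Series("I", index=small_cohort.expression.sample_ids)
        with pytest.raises(ValueError, match="2 distinct"):
            stage_association(small_cohort.expression, small_cohort.catalog,
                              stages)
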