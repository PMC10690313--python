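import numpy as np
import pandas as pd
import pytest

from losirf import (
    Forest,
    LocusMap,
    SignedInteraction,
    aggregate_across_thresholds,
    aggregate_snvs_to_loci,
    local_stability_importance,
    locus_usage,
    permutation_test,
    prediction_screen,
    rank_loci_setaside,
    select_candidates,
)
from losirf.interactions import RITCandidate
from losirf.prioritize import (
    DEFAULT_N_PERM,
    DEFAULT_P_CUTOFF,
    DEFAULT_TOP_LOCI,
    PermutationTestResult,
)
from losirf.stability import InteractionStability

from conftest import make_tree, random_genotypes


class TestAggregateSnvsToLoci:
    def test_partition(self):
        lm = LocusMap({"v1": "L1", "v2": "L1", "v3": "A;B"})
        table = aggregate_snvs_to_loci(["v1", "v2", "v3"], lm)
        assert table == {"L1": ["v1", "v2"], "A;B": ["v3"]}

    def test_duplicates_deduplicated(self):
        lm = LocusMap({"v1": "L1"})
        assert aggregate_snvs_to_loci(["v1", "v1"], lm) == {"L1": ["v1"]}

    def test_unmapped_variant_listed_in_error(self):
        lm = LocusMap({"v1": "L1"})
        with pytest.raises(KeyError, match="v9"):
            aggregate_snvs_to_loci(["v1", "v9"], lm)


def two_locus_forest():
    """Tree 0: splits a (L_A) then b (L_B) on the a+ branch.
    Individuals with a=0 use only L_A on their path."""
    tree = make_tree(
        feature=[0, -1, 1, -1, -1],
        threshold=[0.5, 0, 0.5, 0, 0],
        left=[1, -1, 3, -1, -1],
        right=[2, -1, 4, -1, -1],
        count0=[10, 5, 5, 3, 2],
        count1=[10, 2, 8, 4, 4],
    )
    return Forest([tree], feature_names=["a", "b"])


class TestLocalStabilityImportance:
    def setup_method(self):
        self.forest = two_locus_forest()
        self.lm = LocusMap({"a": "L_A", "b": "L_B"})

    def test_direct_count_on_single_tree(self):
        from losirf import GenotypeMatrix, VariantInfo

        X = GenotypeMatrix(
            individual_ids=["i_both", "i_a_only"],
            variants=[VariantInfo(variant_id="a"), VariantInfo(variant_id="b")],
            dosages=np.array([[2, 2], [0, 0]], dtype=np.int8),
        )
        pair = SignedInteraction([("L_A", "+"), ("L_B", "+")])
        single = SignedInteraction([("L_A", "+")])
        pair_scores = local_stability_importance(self.forest, X, pair, self.lm)
        assert pair_scores.scores.tolist() == [1.0, 0.0]
        single_scores = local_stability_importance(self.forest, X, single, self.lm)
        assert single_scores.scores.tolist() == [1.0, 0.0]
        minus = local_stability_importance(
            self.forest, X, SignedInteraction([("L_A", "-")]), self.lm
        )
        assert minus.scores.tolist() == [0.0, 1.0]

    def test_unused_locus_scores_zero(self):
        from losirf import GenotypeMatrix, VariantInfo

        X = GenotypeMatrix(
            individual_ids=["i1"],
            variants=[VariantInfo(variant_id="a"), VariantInfo(variant_id="b")],
            dosages=np.array([[1, 1]], dtype=np.int8),
        )
        lm = LocusMap({"a": "L_A", "b": "L_B", "c": "L_C"})
        scores = local_stability_importance(
            self.forest, X, SignedInteraction([("L_C", "+")]), lm
        )
        assert scores.scores.tolist() == [0.0]

    def test_anti_monotone_in_order_via_path_audit(self):
        # oracle: walk every tree path explicitly and recount
        from losirf import GenotypeMatrix, VariantInfo, fit_weighted_forest

        gm = random_genotypes(150, 6, seed=21)
        rng = np.random.default_rng(21)
        y = (gm.dosages[:, 0] + rng.random(150) >= 1).astype(int)
        forest = fit_weighted_forest(gm.dosages, y, n_trees=15, seed=22)
        forest.feature_names = gm.variant_ids
        lm = LocusMap({v: f"G{j % 3}" for j, v in enumerate(gm.variant_ids)})
        cache = locus_usage(forest, gm, lm)
        pair = SignedInteraction([("G0", "+"), ("G1", "-")])
        s_pair = cache.lsi(pair)
        s0 = cache.lsi(SignedInteraction([("G0", "+")]))
        s1 = cache.lsi(SignedInteraction([("G1", "-")]))
        assert (s_pair <= np.minimum(s0, s1) + 1e-12).all()
        assert ((s_pair >= 0) & (s_pair <= 1)).all()

        # explicit audit on a few individuals
        X = np.ascontiguousarray(gm.dosages)
        for i in range(10):
            count = 0
            for tree in forest.trees:
                node = 0
                used = set()
                while tree.left[node] >= 0:
                    f = tree.feature[node]
                    locus = lm[gm.variant_ids[f]]
                    if X[i, f] <= tree.threshold[node]:
                        used.add((locus, "-"))
                        node = tree.left[node]
                    else:
                        used.add((locus, "+"))
                        node = tree.right[node]
                if {("G0", "+"), ("G1", "-")} <= used:
                    count += 1
            assert s_pair[i] == pytest.approx(count / forest.n_trees)


class TestRankLoci:
    def test_locus_used_in_every_tree_ranks_first(self):
        from losirf import GenotypeMatrix, VariantInfo

        forest = two_locus_forest()
        lm = LocusMap({"a": "L_A", "b": "L_B"})
        X = GenotypeMatrix(
            individual_ids=["i1", "i2"],
            variants=[VariantInfo(variant_id="a"), VariantInfo(variant_id="b")],
            dosages=np.array([[2, 0], [2, 2]], dtype=np.int8),
        )
        shortlist, table = rank_loci_setaside(forest, X, lm, top_n=2)
        # every individual's path takes a+; L_A+ has mean LSI 1.0
        assert table.iloc[0]["locus"] == "L_A"
        assert table.iloc[0]["sign"] == "+"
        assert table.iloc[0]["mean_lsi"] == 1.0
        assert str(shortlist[0]) == "L_A+"

    def test_default_shortlist_size(self):
        assert DEFAULT_TOP_LOCI == 25

    def test_ties_broken_lexicographically(self):
        from losirf import GenotypeMatrix, VariantInfo

        forest = two_locus_forest()
        lm = LocusMap({"a": "Lx", "b": "La"})
        X = GenotypeMatrix(
            individual_ids=["i1"],
            variants=[VariantInfo(variant_id="a"), VariantInfo(variant_id="b")],
            dosages=np.array([[2, 2]], dtype=np.int8),
        )
        _, table = rank_loci_setaside(forest, X, lm, top_n=4)
        tied = table[table["mean_lsi"] == 1.0]
        assert tied["locus"].tolist() == sorted(tied["locus"].tolist())


class TestPermutationTest:
    def test_null_identity_gives_p_one(self):
        scores = np.zeros(40)
        y = np.array([0, 1] * 20)
        result = permutation_test(scores, y, n_perm=200, seed=0)
        assert result.observed == 0.0
        assert result.p_value == 1.0

    def test_perfect_separation_is_significant(self):
        # oracle: the observed statistic is the maximum attainable, so only
        # permutations reproducing the exact split can match it
        scores = np.concatenate([np.ones(200), np.zeros(200)])
        y = np.concatenate([np.ones(200, int), np.zeros(200, int)])
        result = permutation_test(scores, y, n_perm=10000, seed=1)
        assert result.p_value <= 0.001

    def test_default_n_perm(self):
        assert DEFAULT_N_PERM == 10000

    def test_add_one_rule_keeps_p_positive(self):
        rng = np.random.default_rng(2)
        result = permutation_test(
            rng.random(30), np.array([0, 1] * 15), n_perm=99, seed=3
        )
        assert result.p_value >= 1 / 100

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            permutation_test(np.ones(10), np.ones(10, int), n_perm=10)


def _stab(interaction, s, mip, fsd):
    return InteractionStability(interaction, s, mip, fsd)


class TestSelectCandidates:
    def test_thresholds_applied(self):
        kept = SignedInteraction([("A", "+"), ("B", "+")])
        boundary = SignedInteraction([("A", "+"), ("C", "+")])
        weak = SignedInteraction([("B", "+"), ("C", "+")])
        stability = {
            kept: _stab(kept, 0.6, 0.1, 0.1),
            boundary: _stab(boundary, 0.5, 0.9, 0.9),  # exactly 0.5: excluded
            weak: _stab(weak, 0.8, 0.0, 0.4),  # smip-stability 0: excluded
        }
        out = select_candidates([], stability)
        assert out == [kept]

    def test_no_stable_interactions_warns(self, caplog):
        locus = SignedInteraction([("A", "+")])
        with caplog.at_level("WARNING"):
            out = select_candidates([locus], {})
        assert out == [locus]
        assert "loci only" in caplog.text

    def test_shortlist_and_interactions_deduplicated(self):
        locus = SignedInteraction([("A", "+")])
        pair = SignedInteraction([("A", "+"), ("B", "+")])
        stability = {pair: _stab(pair, 0.9, 0.5, 0.5)}
        out = select_candidates([locus, pair], stability)
        assert out == [locus, pair]


def _ptr(interaction, p, obs=0.1):
    return PermutationTestResult(interaction, obs, p, 10000)


class TestAggregateAcrossThresholds:
    def test_stable_candidate_mean_p(self):
        cand = SignedInteraction([("A", "+")])
        results = {
            0.15: {cand: _ptr(cand, 0.05)},
            0.20: {cand: _ptr(cand, 0.08)},
            0.25: {cand: _ptr(cand, 0.09)},
        }
        report = aggregate_across_thresholds(results)
        row = report.table.iloc[0]
        assert row["stable"]
        assert row["mean_p"] == pytest.approx(0.0733, abs=1e-4)
        assert row["rank"] == 1

    def test_one_bad_run_is_unstable(self):
        cand = SignedInteraction([("A", "+")])
        results = {
            0.15: {cand: _ptr(cand, 0.05)},
            0.20: {cand: _ptr(cand, 0.20)},
            0.25: {cand: _ptr(cand, 0.01)},
        }
        report = aggregate_across_thresholds(results)
        assert not report.table.iloc[0]["stable"]
        assert len(report.sign_collapsed) == 0

    def test_missing_from_one_run_is_unstable(self):
        cand = SignedInteraction([("A", "+")])
        results = {
            0.15: {cand: _ptr(cand, 0.01)},
            0.20: {},
            0.25: {cand: _ptr(cand, 0.01)},
        }
        report = aggregate_across_thresholds(results)
        assert not report.table.iloc[0]["stable"]

    def test_sign_collapse_takes_smaller_p(self):
        plus = SignedInteraction([("A", "+")])
        minus = SignedInteraction([("A", "-")])
        results = {
            x: {plus: _ptr(plus, p1), minus: _ptr(minus, p2)}
            for x, p1, p2 in [(0.15, 0.04, 0.09), (0.20, 0.04, 0.09), (0.25, 0.04, 0.09)]
        }
        report = aggregate_across_thresholds(results)
        row = report.sign_collapsed.iloc[0]
        assert row["components"] == "A"
        assert row["mean_p"] == pytest.approx(0.04)
        assert row["best_signed"] == "A+"

    def test_sign_collapse_never_increases_p(self):
        rng = np.random.default_rng(4)
        cands = [SignedInteraction([("A", s)]) for s in "+-"] + [
            SignedInteraction([("B", s1), ("C", s2)]) for s1 in "+-" for s2 in "+-"
        ]
        results = {
            x: {c: _ptr(c, float(rng.uniform(0.001, 0.09))) for c in cands}
            for x in (0.15, 0.20, 0.25)
        }
        report = aggregate_across_thresholds(results)
        mean_p = report.table.set_index("candidate")["mean_p"]
        for _, row in report.sign_collapsed.iterrows():
            signed_versions = [
                c for c in cands
                if tuple(l for l, _ in c.components) == tuple(row["components"].split(";"))
            ]
            assert row["mean_p"] <= min(mean_p[str(c)] for c in signed_versions) + 1e-12

    def test_default_cutoff(self):
        assert DEFAULT_P_CUTOFF == 0.1


class TestPredictionScreen:
    def test_random_labels_fail_gate(self):
        from losirf import fit_weighted_forest

        rng = np.random.default_rng(5)
        gm = random_genotypes(400, 10, seed=5)
        y = rng.integers(0, 2, 400)
        forest = fit_weighted_forest(gm.dosages[:300], y[:300], n_trees=30, seed=6)
        metrics, gate = prediction_screen(
            forest, gm.dosages[:300], y[:300], gm.dosages[300:], y[300:], seed=0
        )
        assert abs(metrics.loc["sirf", "balanced_accuracy"] - 0.5) < 0.12
        assert not gate or metrics.loc["sirf", "balanced_accuracy"] <= 0.55

    def test_separable_fixture_passes_gate(self):
        from losirf import fit_weighted_forest

        gm = random_genotypes(400, 10, seed=7)
        y = (gm.dosages[:, 3] >= 1).astype(int)
        forest = fit_weighted_forest(gm.dosages[:300], y[:300], n_trees=30, seed=8)
        metrics, gate = prediction_screen(
            forest, gm.dosages[:300], y[:300], gm.dosages[300:], y[300:], seed=0
        )
        assert gate
        assert metrics.loc["sirf", "balanced_accuracy"] == 1.0
        assert set(metrics.index) == {
            "sirf", "lasso_logistic", "ridge_logistic", "random_forest", "svc"
        }

    def test_degenerate_validation_errors(self, stump_forest):
        X = np.zeros((10, 2), dtype=np.int8)
        with pytest.raises(ValueError, match="degenerate"):
            prediction_screen(stump_forest, X, np.arange(10) % 2, X, np.zeros(10, int))
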