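import numpy as np
import pandas as pd
import pytest
from scipy import stats

from losirf import (
    TermGeneLibrary,
    annotation_enrichment,
    co_association_scores,
    edge_connectivity_p,
    fisher_exact_2x2,
    read_gmt,
    tf_integrated_rank,
)


class TestCoAssociation:
    def test_jaccard_example(self):
        # A and B each enriched in 3 terms, sharing 2 -> R = 2/4
        gene_terms = {
            "A": {"t1", "t2", "t3"},
            "B": {"t2", "t3", "t4"},
        }
        table = co_association_scores(gene_terms)
        assert table.iloc[0]["R"] == pytest.approx(0.5)
        assert table.iloc[0]["n_intersection"] == 2
        assert table.iloc[0]["n_union"] == 4

    def test_disjoint_and_empty_union_conventions(self):
        gene_terms = {"A": {"t1"}, "B": {"t2"}, "C": set(), "D": set()}
        table = co_association_scores(gene_terms).set_index(["gene_a", "gene_b"])
        assert table.loc[("A", "B"), "R"] == 0.0  # disjoint, nonempty union
        assert table.loc[("C", "D"), "R"] == 0.0  # empty union -> 0 by convention

    @pytest.mark.parametrize("g,expected", [(3, 3), (21, 210), (382, 72771)])
    def test_pair_count(self, g, expected):
        genes = {f"G{k:03d}": {"t"} for k in range(g)}
        assert len(co_association_scores(genes)) == expected

    def test_symmetry_and_unit_range(self):
        rng = np.random.default_rng(0)
        universe = [f"g{k}" for k in range(15)]
        terms = {
            g: {f"t{j}" for j in rng.choice(20, size=rng.integers(0, 8), replace=False)}
            for g in universe
        }
        table = co_association_scores(terms)
        assert ((table["R"] >= 0) & (table["R"] <= 1)).all()
        # R == 1 iff term sets equal and nonempty
        for row in table.itertuples():
            a = {t.upper() for t in terms[row.gene_a.lower()]}
            b = {t.upper() for t in terms[row.gene_b.lower()]}
            if row.R == 1.0:
                assert a == b and a
            elif a == b and a:
                assert row.R == 1.0

    def test_empirical_p_counts_extremes(self):
        gene_terms = {"A": {"t1", "t2"}, "B": {"t1", "t2"}, "C": {"t9"}, "D": set()}
        table = co_association_scores(gene_terms)
        dev = np.abs(table["R"] - table["R"].mean())
        for _, row in table.iterrows():
            expected = (dev >= abs(row["R"] - table["R"].mean()) - 1e-12).mean()
            assert row["p_empirical"] == pytest.approx(expected)

    def test_too_few_genes(self):
        with pytest.raises(ValueError, match="at least 2"):
            co_association_scores({"A": {"t"}})


class TestAnnotationEnrichment:
    def test_enrichment_score_ratio(self):
        table = annotation_enrichment(
            {"locus1": {"intronic": 5, "exonic": 5}},
            {"intronic": 250, "exonic": 750},
        )
        row = table.set_index("annotation").loc["intronic"]
        assert row["enrichment"] == pytest.approx((5 / 10) / (250 / 1000))

    def test_no_enrichment_gives_unit_score_and_p_one(self):
        table = annotation_enrichment(
            {"locus1": {"a": 5, "b": 5}}, {"a": 500, "b": 500}
        )
        row = table.set_index("annotation").loc["a"]
        assert row["enrichment"] == pytest.approx(1.0)
        assert row["p_fisher"] == pytest.approx(1.0)

    def test_printed_table_compatibility_flag(self):
        counts = {"locus1": {"a": 5, "b": 5}}
        ref = {"a": 250, "b": 750}
        standard = annotation_enrichment(counts, ref)
        printed = annotation_enrichment(counts, ref, printed_table=True)
        assert not np.allclose(
            standard["p_fisher"].to_numpy(), printed["p_fisher"].to_numpy()
        )

    def test_locus_exceeding_reference_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            annotation_enrichment({"l": {"a": 10}}, {"a": 5})

    def test_zero_reference_errors(self):
        with pytest.raises(ValueError, match="zero"):
            annotation_enrichment({"l": {}}, {})


def _oracle_two_sided_fisher(a, b, c, d):
    """Exact hypergeometric enumeration: sum the probabilities of all tables
    with the observed margins whose probability does not exceed the observed
    table's (with the standard relative tolerance)."""
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, col1, row1)
    p_obs = stats.hypergeom.pmf(a, n, col1, row1)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())


class TestFisherOracle:
    def test_example_table(self):
        # 2x2 table (5,5,245,745)
        expected = _oracle_two_sided_fisher(5, 5, 245, 745)
        assert fisher_exact_2x2(5, 5, 245, 745) == pytest.approx(expected, rel=1e-9)

    def test_all_small_tables(self):
        # exhaustive check for all tables with total <= 25
        for n in range(1, 26):
            for r in range(n + 1):
                for c in range(n + 1):
                    for a in range(max(0, r + c - n), min(r, c) + 1):
                        b, cc, d = r - a, c - a, n - r - c + a
                        got = fisher_exact_2x2(a, b, cc, d)
                        want = _oracle_two_sided_fisher(a, b, cc, d)
                        assert got == pytest.approx(want, rel=1e-9, abs=1e-12)


class TestTfIntegratedRank:
    def test_scaled_rank_definition(self):
        # shared integer ranks 1,2,2,4 -> scaled 0.25, 0.5, 0.5, 1.0
        lib = pd.DataFrame(
            {"tf": ["T1", "T2", "T3", "T4"], "p_value": [0.001, 0.01, 0.01, 0.5]}
        )
        table = tf_integrated_rank({"lib1": lib}).set_index("tf")
        assert table.loc["T1", "mean_scaled_rank"] == pytest.approx(0.25)
        assert table.loc["T2", "mean_scaled_rank"] == pytest.approx(0.5)
        assert table.loc["T3", "mean_scaled_rank"] == pytest.approx(0.5)
        assert table.loc["T4", "mean_scaled_rank"] == pytest.approx(1.0)

    def test_significant_library_count_dominates(self):
        libs = {}
        for k in range(3):
            libs[f"lib{k}"] = pd.DataFrame(
                {"tf": ["A", "B"], "p_value": [0.01, 0.5 if k < 2 else 0.01]}
            )
        # A significant in 3 libraries, B in 1; B has no chance whatever its rank
        table = tf_integrated_rank(libs)
        assert table.iloc[0]["tf"] == "A"
        assert table.iloc[0]["n_significant"] == 3

    def test_single_library_orders_by_p(self):
        lib = pd.DataFrame({"tf": ["X", "Y", "Z"], "p_value": [0.03, 0.01, 0.02]})
        table = tf_integrated_rank({"l": lib})
        assert table["tf"].tolist() == ["Y", "Z", "X"]
        assert table["final_rank"].tolist() == [1, 2, 3]

    def test_empty_input_errors(self):
        with pytest.raises(ValueError, match="at least one"):
            tf_integrated_rank({})
        with pytest.raises(ValueError, match="empty"):
            tf_integrated_rank({"l": pd.DataFrame({"tf": [], "p_value": []})})


def _edges(rows):
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"])


class TestEdgeConnectivity:
    def test_unique_maximum(self):
        table = _edges([("a", "b", 5.0), ("a", "c", 1.0), ("b", "c", 2.0), ("c", "d", 3.0)])
        assert edge_connectivity_p(table, ("a", "b")) == pytest.approx(1 / 4)

    def test_all_equal_weights(self):
        table = _edges([("a", "b", 1.0), ("a", "c", 1.0), ("b", "c", 1.0)])
        assert edge_connectivity_p(table, ("b", "c")) == pytest.approx(1.0)

    def test_toy_network_matches_enumeration(self):
        rng = np.random.default_rng(1)
        genes = "abcde"
        rows = [
            (genes[i], genes[j], float(rng.normal()))
            for i in range(5)
            for j in range(i + 1, 5)
        ]
        table = _edges(rows)
        weights = np.array([w for _, _, w in rows])
        for (ga, gb, w) in rows:
            expected = (weights >= w - 1e-12).mean()
            assert edge_connectivity_p(table, (ga, gb)) == pytest.approx(expected)

    def test_difference_mode_two_tailed(self):
        rng = np.random.default_rng(2)
        genes = "abcd"
        pairs = [(genes[i], genes[j]) for i in range(4) for j in range(i + 1, 4)]
        w1 = rng.normal(size=len(pairs))
        w2 = rng.normal(size=len(pairs))
        t1 = _edges([(a, b, w) for (a, b), w in zip(pairs, w1)])
        t2 = _edges([(a, b, w) for (a, b), w in zip(pairs, w2)])
        z1 = (w1 - w1.mean()) / w1.std()
        z2 = (w2 - w2.mean()) / w2.std()
        diff = np.abs(z1 - z2)
        for k, pair in enumerate(pairs):
            expected = (diff >= diff[k] - 1e-12).mean()
            got = edge_connectivity_p([t1, t2], pair, mode="difference")
            assert got == pytest.approx(expected)

    def test_absent_pair_errors(self):
        table = _edges([("a", "b", 1.0)])
        with pytest.raises(KeyError, match="absent"):
            edge_connectivity_p(table, ("a", "z"))


class TestGmt:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "lib.gmt"
        path.write_text("term1\tdesc\tGene1\tgene2\nterm2\t.\tGENE3\n")
        lib = read_gmt(path)
        assert lib.terms["term1"] == {"GENE1", "GENE2"}
        assert lib.gene_terms()["GENE3"] == {"term2"}

    def test_duplicate_term_errors(self, tmp_path):
        path = tmp_path / "dup.gmt"
        path.write_text("t\td\tA\nt\td\tB\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_gmt(path)

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            TermGeneLibrary("x", {"t": frozenset()})
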