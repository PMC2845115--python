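"""Cohort analysis: frequencies, co-occurrence, ratios, concordance, chi-square."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from maldiplex import (
    chisq_association,
    concordance,
    cooccurrence,
    expected_double_frequency,
    frequency_table,
    load_reference,
    mutation_ratio,
    ratio_summary,
    records_from_counts,
    select_assays,
)
from maldiplex.caller import MutationRecord


@pytest.fixture(scope="module")
def reference():
    return load_reference()


@pytest.fixture(scope="module")
def reference_freq_table(reference):
    records = records_from_counts(reference.mutation_counts)
    return frequency_table(records, reference.n_samples)


class TestFrequencyTable:
    def test_reference_gene_totals(self, reference_freq_table):
        pg = reference_freq_table.per_gene.set_index("gene")
        assert pg.loc["KRAS", "count_sum"] == 104
        assert pg.loc["KRAS", "frequency"] * 100 == pytest.approx(43.5, abs=0.05)
        assert pg.loc["PIK3CA", "frequency"] * 100 == pytest.approx(20.1, abs=0.05)

    def test_empty_records_all_zero(self):
        ft = frequency_table([], 100)
        assert len(ft.per_mutation) == 0
        assert ft.overall_pct == 0.0

    def test_distinct_sample_counting(self):
        # one sample mutated twice in one gene counts once for the gene
        records = [
            MutationRecord("s1", "PIK3CA", "E545K", 0.3),
            MutationRecord("s1", "PIK3CA", "H1047R", 0.2),
            MutationRecord("s2", "PIK3CA", "E545K", 0.4),
        ]
        ft = frequency_table(records, 10)
        pg = ft.per_gene.set_index("gene")
        assert pg.loc["PIK3CA", "count_sum"] == 3
        assert pg.loc["PIK3CA", "count_distinct"] == 2
        assert ft.gene_frequency("PIK3CA") == pytest.approx(0.2)
        assert pg.loc["PIK3CA", "multiple_mutation_pct"] == pytest.approx(50.0)

    def test_matches_direct_tally_oracle(self):
        rng = np.random.default_rng(5)
        genes = ["KRAS", "BRAF", "PIK3CA"]
        records = []
        for s in range(60):
            for g in genes:
                if rng.random() < 0.3:
                    records.append(MutationRecord(f"s{s}", g, "X1Y", 0.5))
        ft = frequency_table(records, 60)
        for g in genes:
            expected = len({r.sample_id for r in records if r.gene == g}) / 60
            assert ft.gene_frequency(g) == pytest.approx(expected)
        burden = len({r.sample_id for r in records}) / 60 * 100
        assert ft.overall_pct == pytest.approx(burden)

    def test_gene_frequency_bounds_mutation_frequency(self, reference_freq_table):
        ft = reference_freq_table
        for _, row in ft.per_mutation.iterrows():
            assert ft.gene_frequency(row["gene"]) >= row["frequency"] - 1e-12

    def test_more_samples_than_cohort_rejected(self):
        records = [MutationRecord(f"s{i}", "KRAS", "G12D", 0.5) for i in range(5)]
        with pytest.raises(ValueError):
            frequency_table(records, 4)


class TestCooccurrence:
    def test_product_rule_from_reference_single_frequencies(self, reference):
        singles = reference.gene_single_freq_pct
        met_kras = expected_double_frequency(
            singles["MET"] / 100, singles["KRAS"] / 100
        )
        assert met_kras * 100 == pytest.approx(1.44, abs=0.005)

    def test_zero_frequency_gene_has_zero_expectation(self):
        records = [MutationRecord("s1", "KRAS", "G12D", 0.5)]
        table = cooccurrence(records, 10)
        assert (table.table["expected"] >= 0).all()
        assert expected_double_frequency(0.0, 0.5) == 0.0

    def test_actual_counts_distinct_double_mutant_samples(self):
        records = [
            MutationRecord("s1", "KRAS", "G12D", 0.5),
            MutationRecord("s1", "PIK3CA", "E545K", 0.2),
            MutationRecord("s2", "KRAS", "G12V", 0.5),
            MutationRecord("s3", "PIK3CA", "E545K", 0.2),
        ]
        table = cooccurrence(records, 10)
        actual, expected = table.pair("KRAS", "PIK3CA")
        assert actual == pytest.approx(0.1)
        assert expected == pytest.approx(0.2 * 0.2)


class TestMutationRatio:
    def r(self, sample, gene, aa, f):
        return MutationRecord(sample, gene, aa, f)

    def test_double_mutant_primary_ratio(self):
        m1 = self.r("x", "KRAS", "G12D", 0.45)
        m2 = self.r("x", "PIK3CA", "H1047R", 0.24)
        assert round(mutation_ratio(m1, m2), 2) == 1.88

    def test_equal_fractions_give_unity(self):
        m1 = self.r("x", "KRAS", "G12D", 0.3)
        m2 = self.r("x", "PIK3CA", "E545K", 0.3)
        assert mutation_ratio(m1, m2) == pytest.approx(1.0)

    def test_cross_sample_comparison_rejected(self):
        with pytest.raises(ValueError):
            mutation_ratio(
                self.r("x", "KRAS", "G12D", 0.3), self.r("y", "PIK3CA", "E545K", 0.3)
            )


class TestRatioSummary:
    def test_dominance_share_from_reference_bands(self, reference):
        ratios = []
        rng = np.random.default_rng(2)
        for band in reference.kras_pik3ca_ratio_bands:
            ratios.extend(
                rng.uniform(band["low"], band["high"], band["n"]).tolist()
            )
        # the top band's lower edge is exclusive of the threshold itself
        summary = ratio_summary(ratios, threshold=1.25)
        assert summary.n == 31
        assert summary.n_above == 22
        assert round(summary.pct_above) == 71

    def test_identical_ratios_median(self):
        summary = ratio_summary([1.6] * 5)
        assert summary.median == pytest.approx(1.6)
        assert summary.mean == pytest.approx(1.6)

    @settings(max_examples=25, deadline=None)
    @given(
        ratios=st.lists(
            st.floats(min_value=0.01, max_value=10.0), min_size=1, max_size=40
        )
    )
    def test_matches_sorting_oracle(self, ratios):
        summary = ratio_summary(ratios)
        srt = sorted(ratios)
        assert summary.median == pytest.approx(float(np.median(srt)))
        assert summary.mean == pytest.approx(sum(srt) / len(srt))
        assert summary.n_above == sum(1 for r in ratios if r > 1.25)
        assert sum(summary.band_counts.values()) == len(ratios)


class TestConcordance:
    def reports(self, n_pairs, discordant_idx=()):
        prim, node = {}, {}
        for i in range(n_pairs):
            sid = f"pair{i}"
            muts = [MutationRecord(sid, "KRAS", "G12D", 0.4)]
            prim[sid] = muts
            node[sid] = [] if i in discordant_idx else list(muts)
        return prim, node

    def test_35_of_39_pairs_identical(self):
        prim, node = self.reports(39, discordant_idx=(0, 5, 11, 20))
        report = concordance(prim, node)
        assert report.n_identical == 35
        assert report.percent_concordant == pytest.approx(89.7, abs=0.05)
        assert len(report.primary_only) == 4
        assert report.node_only == ()

    def test_identical_pairs_are_fully_concordant(self):
        prim, node = self.reports(10)
        assert concordance(prim, node).percent_concordant == 100.0

    def test_order_of_records_is_irrelevant(self):
        prim = {
            "s": [
                MutationRecord("s", "KRAS", "G12D", 0.4),
                MutationRecord("s", "PIK3CA", "E545K", 0.2),
            ]
        }
        node = {"s": prim["s"][::-1]}
        assert concordance(prim, node).percent_concordant == 100.0

    def test_double_mutant_ratios_reported_for_both_members(self):
        prim = {
            "s": [
                MutationRecord("s", "KRAS", "G12D", 0.45),
                MutationRecord("s", "PIK3CA", "H1047R", 0.24),
            ]
        }
        node = {
            "s": [
                MutationRecord("s", "KRAS", "G12D", 0.44),
                MutationRecord("s", "PIK3CA", "H1047R", 0.27),
            ]
        }
        report = concordance(prim, node)
        prim_ratio, node_ratio = report.double_mutant_ratios["s"]
        assert round(prim_ratio, 2) == 1.88
        assert round(node_ratio, 2) == 1.63

    def test_dropped_second_mutation_gives_undefined_node_ratio(self):
        prim = {
            "s": [
                MutationRecord("s", "KRAS", "G12C", 0.37),
                MutationRecord("s", "PIK3CA", "H1047R", 0.21),
            ]
        }
        node = {"s": [MutationRecord("s", "KRAS", "G12C", 0.15)]}
        report = concordance(prim, node)
        assert report.double_mutant_ratios["s"][1] is None

    def test_unpaired_ids_rejected(self):
        prim, node = self.reports(3)
        del node["pair1"]
        with pytest.raises(ValueError):
            concordance(prim, node)


class TestChisq:
    def test_proportional_table_statistic_zero(self):
        stat, p = chisq_association([[10, 10], [10, 10]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_scaled_proportional_rows_statistic_zero(self):
        stat, _ = chisq_association([[20, 30], [40, 60]])
        assert stat == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(
        cells=st.lists(st.integers(min_value=1, max_value=500), min_size=4, max_size=4)
    )
    def test_matches_closed_form(self, cells):
        table = np.array(cells, dtype=float).reshape(2, 2)
        stat, _ = chisq_association(table)
        total = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
        oracle = float(((table - expected) ** 2 / expected).sum())
        assert stat == pytest.approx(oracle)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chisq_association([[0, 0], [5, 7]])


class TestSelectAssays:
    def test_maximal_threshold_selects_nothing(self, reference_freq_table, panel):
        assert select_assays(reference_freq_table, panel, threshold=1.0) == []

    def test_one_percent_gene_level_selection(self, reference_freq_table, panel):
        selected = select_assays(
            reference_freq_table, panel, level="gene", threshold=0.01
        )
        genes = {panel.assays[a].gene for a in selected}
        assert genes == {"KRAS", "PIK3CA", "BRAF", "MET", "NRAS"}

    def test_tiny_threshold_keeps_all_mutated_genes(self, reference_freq_table, panel):
        selected = select_assays(
            reference_freq_table, panel, level="gene", threshold=1e-9
        )
        genes = {panel.assays[a].gene for a in selected}
        # every panel gene with nonzero cohort frequency
        assert genes == {"KRAS", "PIK3CA", "BRAF", "MET", "NRAS"}

    def test_assay_level_uses_specific_mutations(self, reference_freq_table, panel):
        selected = select_assays(
            reference_freq_table, panel, level="assay", threshold=0.05
        )
        # only KRAS-G12D (16.7%), KRAS-G13D (9.6%), KRAS-G12V (8.4%),
        # BRAF-V600E (11.7%), PIK3CA-E545K (5.0%), PIK3CA-H1047R (5.9%)
        assert "KRAS_4" in selected  # G13D
        assert "PIK3CA_1" not in selected  # R88Q at 2.1%
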