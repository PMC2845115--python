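"""Panel model: oligo masses, analytes, validation, pool conflicts."""

import json
from collections import Counter

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from maldiplex import (
    MassTable,
    Panel,
    analytes_for,
    load_panel,
    oligo_mass,
    pool_conflicts,
    write_panel,
)
from maldiplex.errors import (
    ComplexGroupError,
    DuplicateAssayError,
    InvalidSequenceError,
    MassTableError,
    PoolSizeError,
    UnknownBaseError,
)

from conftest import make_assay

SEQ = st.text(alphabet="ACGT", min_size=0, max_size=40)


def mass_oracle(sequence: str, mt: MassTable) -> float:
    """Independent mass computation: per-base counts times residue masses."""
    counts = Counter(sequence)
    return mt.terminal_adjustment + sum(
        n * mt.residue_mass[b] for b, n in counts.items()
    )


class TestOligoMass:
    def test_empty_sequence_is_terminal_adjustment(self, mass_table):
        assert oligo_mass("", mass_table) == mass_table.terminal_adjustment

    def test_homopolymer(self, mass_table):
        expected = 10 * mass_table.residue_mass["A"] + mass_table.terminal_adjustment
        assert oligo_mass("A" * 10, mass_table) == pytest.approx(expected)

    def test_mixed_23mer_matches_oracle(self, mass_table):
        seq = "ACGTACGTGGTTCCAATGCGTAC"
        assert len(seq) == 23
        assert oligo_mass(seq, mass_table) == pytest.approx(
            mass_oracle(seq, mass_table)
        )

    @settings(max_examples=50, deadline=None)
    @given(seq=SEQ)
    def test_matches_counting_oracle(self, mass_table, seq):
        assert oligo_mass(seq, mass_table) == pytest.approx(
            mass_oracle(seq, mass_table)
        )

    def test_invalid_symbol_names_position(self, mass_table):
        with pytest.raises(InvalidSequenceError) as exc:
            oligo_mass("ACGTNACGT", mass_table)
        assert exc.value.position == 4


class TestMassTable:
    def test_nonpositive_residue_rejected(self, mass_table):
        bad = dict(mass_table.residue_mass, A=-1.0)
        with pytest.raises(MassTableError):
            MassTable(bad, mass_table.terminator_mass, 18.02)

    def test_close_terminators_rejected(self, mass_table):
        bad = dict(mass_table.terminator_mass)
        bad["C"] = bad["A"] + 2.0
        with pytest.raises(MassTableError):
            MassTable(mass_table.residue_mass, bad, 18.02)

    def test_roundtrip_dict(self, mass_table):
        assert MassTable.from_dict(mass_table.to_dict()) == mass_table


class TestAnalytes:
    def test_single_mutant_gives_three_analytes(self, mass_table):
        assay = make_assay("a1", "ACGT" * 5, wt="A", muts={"T": "X1Y"})
        analytes = analytes_for(assay, mass_table)
        assert len(analytes) == 3
        wt = next(a for a in analytes if a.role == "wt_extension")
        mut = next(a for a in analytes if a.role == "mut_extension")
        gap = abs(
            mass_table.terminator_mass["A"] - mass_table.terminator_mass["T"]
        )
        assert abs(wt.mass - mut.mass) == pytest.approx(gap)

    def test_three_mutants_give_five_distinct_analytes(self, mass_table):
        assay = make_assay(
            "a1", "ACGT" * 5, wt="G", muts={"A": "a", "C": "c", "T": "t"}
        )
        analytes = analytes_for(assay, mass_table)
        assert len(analytes) == 5
        masses = [a.mass for a in analytes]
        assert len(set(masses)) == 5

    def test_masses_match_brute_force(self, panel):
        mt = panel.mass_table
        for assay in panel.assays.values():
            uep = mass_oracle(assay.primer_seq, mt)
            for an in analytes_for(assay, mt):
                if an.role == "unextended":
                    assert an.mass == pytest.approx(uep)
                else:
                    assert an.mass == pytest.approx(
                        uep + mt.terminator_mass[an.label]
                    )

    def test_uep_lightest_and_masses_increasing(self, panel):
        for assay in panel.assays.values():
            analytes = analytes_for(assay, panel.mass_table)
            uep = analytes[0]
            assert uep.role == "unextended"
            assert all(uep.mass < a.mass for a in analytes[1:])


def two_pool_panel_dict(mass_table, mutate=None):
    assays = [
        make_assay("a1", "A" * 15).to_dict(),
        make_assay("a2", "A" * 17).to_dict(),
        make_assay("a3", "A" * 19).to_dict(),
    ]
    d = {
        "name": "tiny",
        "max_plex": 9,
        "mass_table": mass_table.to_dict(),
        "pools": {"p1": assays[:2], "p2": assays[2:]},
    }
    if mutate:
        mutate(d)
    return d


class TestLoadPanel:
    def test_well_formed_two_pool_fixture(self, tmp_path, mass_table):
        path = tmp_path / "panel.json"
        path.write_text(json.dumps(two_pool_panel_dict(mass_table)))
        panel = load_panel(path)
        assert len(panel.pools) == 2
        assert set(panel.assays) == {"a1", "a2", "a3"}

    def test_duplicate_assay_id(self, tmp_path, mass_table):
        def dup(d):
            d["pools"]["p2"].append(d["pools"]["p1"][0])

        path = tmp_path / "panel.json"
        path.write_text(json.dumps(two_pool_panel_dict(mass_table, dup)))
        with pytest.raises(DuplicateAssayError):
            load_panel(path)

    def test_unknown_base(self, tmp_path, mass_table):
        def bad(d):
            d["pools"]["p1"][0]["wt_base"] = "X"
            d["pools"]["p1"][0]["mut_alleles"] = {"T": "X1Y"}

        path = tmp_path / "panel.json"
        path.write_text(json.dumps(two_pool_panel_dict(mass_table, bad)))
        with pytest.raises(UnknownBaseError):
            load_panel(path)

    def test_pool_size_above_max_plex(self, tmp_path, mass_table):
        def overflow(d):
            d["max_plex"] = 1

        path = tmp_path / "panel.json"
        path.write_text(json.dumps(two_pool_panel_dict(mass_table, overflow)))
        with pytest.raises(PoolSizeError):
            load_panel(path)

    def test_dangling_complex_group(self, tmp_path, mass_table):
        def orphan(d):
            d["pools"]["p1"][0]["kind"] = "complex"
            d["pools"]["p1"][0]["complex_group"] = "lonely"
            d["pools"]["p1"][0]["codon_ref"] = "GGT"
            d["pools"]["p1"][0]["codon_pos"] = 1

        path = tmp_path / "panel.json"
        path.write_text(json.dumps(two_pool_panel_dict(mass_table, orphan)))
        with pytest.raises(ComplexGroupError):
            load_panel(path)

    def test_shipped_colon_panel(self, panel):
        assert len(panel.pools) == 6
        assert len(panel.assays) == 25
        for pool_id, ids in panel.pools.items():
            assert 1 <= len(ids) <= panel.max_plex
            assert not pool_conflicts(
                panel.pool_assays(pool_id),
                panel.mass_table,
                min_gap=16.0,
                include_adducts=True,
            )

    def test_write_load_roundtrip(self, tmp_path, panel):
        path = tmp_path / "roundtrip.json"
        write_panel(panel, path)
        again = load_panel(path)
        assert again.to_dict() == panel.to_dict()


class TestPoolConflicts:
    def test_widely_spaced_assays_have_no_conflicts(self, mass_table):
        a = make_assay("a1", "A" * 15)
        b = make_assay("a2", "A" * 17)  # ~626 Da heavier
        assert pool_conflicts([a, b], mass_table, min_gap=20.0) == []

    def test_identical_uep_masses_conflict_at_zero(self, mass_table):
        a = make_assay("a1", "ACGT" * 4)
        b = make_assay("a2", "TGCA" * 4)  # same composition, same mass
        conflicts = pool_conflicts([a, b], mass_table, min_gap=20.0)
        assert any(d == 0.0 for _, _, d in conflicts)

    @settings(max_examples=25, deadline=None)
    @given(data=st.data())
    def test_matches_all_pairs_brute_force(self, mass_table, data):
        n = data.draw(st.integers(min_value=2, max_value=6))
        assays = [
            make_assay(
                f"a{i}",
                data.draw(st.text(alphabet="ACGT", min_size=15, max_size=22)),
            )
            for i in range(n)
        ]
        min_gap = data.draw(st.floats(min_value=1.0, max_value=400.0))
        got = pool_conflicts(assays, mass_table, min_gap=min_gap)
        expected = set()
        analytes = {a.assay_id: analytes_for(a, mass_table) for a in assays}
        for i in range(n):
            for j in range(i + 1, n):
                for x in analytes[assays[i].assay_id]:
                    for y in analytes[assays[j].assay_id]:
                        if abs(x.mass - y.mass) < min_gap:
                            expected.add((x.assay_id, x.label, y.assay_id, y.label))
        assert {
            (x.assay_id, x.label, y.assay_id, y.label) for x, y, _ in got
        } == expected

    def test_empty_iff_all_gaps_at_least_min_gap(self, panel):
        for pool_id in panel.pools:
            assays = panel.pool_assays(pool_id)
            assert pool_conflicts(assays, panel.mass_table, min_gap=16.0) == []
            # enormous min_gap must flag every cross-assay pair
            huge = pool_conflicts(assays, panel.mass_table, min_gap=1e6)
            n_analytes = [len(analytes_for(a, panel.mass_table)) for a in assays]
            total_pairs = sum(
                n_analytes[i] * n_analytes[j]
                for i in range(len(assays))
                for j in range(i + 1, len(assays))
            )
            assert len(huge) == total_pairs
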