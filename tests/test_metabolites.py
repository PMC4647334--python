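"""Metabolite-reaction-gene tracing, consistency calls and the packaged
strong-binder table."""

import numpy as np
import pandas as pd
import pytest
from conftest import make_de

import inducemap as im
from inducemap import metabolites as ma
from inducemap.network import make_network

INDUCERS = [f"I{j}" for j in range(1, 11)]


def toy_net():
    return make_network([
        ("R1", "A + B => M", "enzyme one", ["gA"], None),
        ("R2", "M + C => D", "enzyme two", ["gB", "gC"], None),
        ("R3", "E <=> F", "enzyme three", ["gD"], None),
        ("R4", "F => M2", None, [], None),
    ])


class TestReactionsOf:
    def test_absent_metabolite_empty_list(self):
        assert im.reactions_of("ghost", toy_net()) == []

    def test_product_and_reactant_occurrences_found(self):
        hits = {r.id for r in im.reactions_of("M", toy_net())}
        assert hits == {"R1", "R2"}

    def test_reversible_reaction_matches_either_side(self):
        assert {r.id for r in im.reactions_of("E", toy_net())} == {"R3"}
        assert {r.id for r in im.reactions_of("F", toy_net())} == {"R3", "R4"}

    def test_linear_scan_oracle(self, study):
        for met in sorted(study.network.metabolites)[:25]:
            brute = [r.id for r in study.network.reactions
                     if met in r.reactants | r.products]
            assert [r.id for r in im.reactions_of(met, study.network)] == brute


class TestBuildTable:
    def test_single_association_row_shape(self):
        de = make_de({"gA": {"I1": 1.0}}, INDUCERS)
        table = im.build_table(["A"], toy_net(), de)
        assert len(table) == 1
        assert len(ma.inducer_columns(table)) == 10

    def test_multi_gene_association_fans_out_rows(self):
        de = make_de({"gB": {}, "gC": {}}, INDUCERS)
        table = im.build_table(["C"], toy_net(), de)
        assert sorted(table["gene"]) == ["gB", "gC"]

    def test_cells_missing_unless_significant(self):
        seven = {f"I{j}": -1.0 for j in range(1, 8)}
        de = make_de({"gA": seven}, INDUCERS)
        table = im.build_table(["A"], toy_net(), de)
        cells = table[ma.inducer_columns(table)].iloc[0]
        assert cells.notna().sum() == 7
        assert cells.isna().sum() == 3

    def test_membership_invariant(self, study, study_de):
        mets = list(study.config.probe_metabolites)
        table = im.build_table(mets, study.network, study_de)
        equations = {r.equation(): r for r in study.network.reactions}
        for _, row in table.iterrows():
            rxn = equations[row["reaction"]]
            assert row["metabolite"] in rxn.reactants | rxn.products

    def test_probe_metabolite_rows_match_network(self, study, study_de):
        for probe in study.config.probe_metabolites:
            table = im.build_table([probe], study.network, study_de)
            n_rows = sum(max(len(r.genes), 1)
                         for r in study.network.reactions_of(probe))
            assert len(table) == n_rows


class TestClassifyConsistency:
    def test_all_negative_down_consistent(self):
        de = make_de({"gA": {"I1": -1.0, "I2": -2.0}}, INDUCERS)
        calls = im.classify_consistency(im.build_table(["A"], toy_net(), de))
        assert calls["A"] == "down_consistent"

    def test_all_positive_up_consistent(self):
        de = make_de({"gA": {"I1": 1.0, "I2": 2.0}}, INDUCERS)
        calls = im.classify_consistency(im.build_table(["A"], toy_net(), de))
        assert calls["A"] == "up_consistent"

    def test_single_opposite_cell_makes_mixed(self):
        de = make_de({"gA": {"I1": -1.0, "I2": -2.0, "I3": 0.5}}, INDUCERS)
        calls = im.classify_consistency(im.build_table(["A"], toy_net(), de))
        assert calls["A"] == "mixed"

    def test_no_cells_no_data(self):
        de = make_de({"gD": {}}, INDUCERS)
        calls = im.classify_consistency(im.build_table(["M2"], toy_net(), de))
        assert calls["M2"] == "no_data"

    def test_invariant_to_row_and_column_order(self, rng):
        de = make_de({"gA": {"I1": -1.0}, "gB": {"I2": 1.0}, "gC": {"I3": 1.0}},
                     INDUCERS)
        table = im.build_table(["M", "A", "C"], toy_net(), de)
        base = im.classify_consistency(table)
        shuffled = table.sample(frac=1, random_state=1)
        cols = ma.META_COLUMNS + list(rng.permutation(ma.inducer_columns(table)))
        assert im.classify_consistency(shuffled[cols]) == base


class TestRowStats:
    def test_single_cell(self):
        de = make_de({"gA": {"I4": -1.5}}, INDUCERS)
        table = im.build_table(["A"], toy_net(), de)
        assert im.row_stats(table, "gA") == (-1.5, -1.5, -1.5, 1)

    def test_absent_gene_raises(self):
        de = make_de({"gA": {}}, INDUCERS)
        table = im.build_table(["A"], toy_net(), de)
        with pytest.raises(KeyError):
            im.row_stats(table, "nope")

    def test_brute_force_recount(self, study, study_de):
        mets = list(study.config.probe_metabolites)
        table = im.build_table(mets, study.network, study_de)
        for gene in table["gene"].dropna().unique():
            cells = table.loc[table["gene"] == gene,
                              ma.inducer_columns(table)].to_numpy(float).ravel()
            cells = cells[~np.isnan(cells)]
            if cells.size == 0:
                continue
            lo, hi, mean, n = im.row_stats(table, gene)
            assert (lo, hi, n) == (cells.min(), cells.max(), cells.size)
            assert mean == pytest.approx(cells.mean())


class TestStrongBinderFixture:
    def test_six_metabolites(self):
        table = im.load_table2_fixture()
        assert table["metabolite"].nunique() == 6
        assert set(table["metabolite"]) == {"H2SO3", "SLF", "UPGIII",
                                            "PETHM", "T3P1", "TAUR"}

    def test_consistency_split_four_down_two_up(self):
        calls = im.classify_consistency(im.load_table2_fixture())
        down = {m for m, c in calls.items() if c == "down_consistent"}
        up = {m for m, c in calls.items() if c == "up_consistent"}
        assert down == {"H2SO3", "SLF", "UPGIII", "TAUR"}
        assert up == {"PETHM", "T3P1"}

    @pytest.mark.parametrize("gene,lo,hi,n", [
        ("AO090001000571", -4.61, -1.74, 10),  # sulfite reductase
        ("AO090003000798", -4.26, -1.52, 9),   # sulfate transporter
        ("AO090020000339", -3.18, -1.37, 10),  # UPG-III methyltransferase
        ("AO090103000073", 0.74, 1.28, 10),    # phospholipase C
        ("AO090023000345", 0.98, 1.33, 8),     # transketolase
        ("AO090023000531", -2.1, -1.4, 7),     # taurine dioxygenase
    ])
    def test_row_extremes_match_printed_cells(self, gene, lo, hi, n):
        table = im.load_table2_fixture()
        got_lo, got_hi, _, got_n = im.row_stats(table, gene)
        assert (got_lo, got_hi, got_n) == (lo, hi, n)

    def test_missing_cell_pattern(self):
        table = im.load_table2_fixture()
        taur = table[table["gene"] == "AO090023000531"].iloc[0]
        missing = {c for c in ma.inducer_columns(table)
                   if pd.isna(taur[c])}
        assert missing == {"O-GMH", "SOP", "O-X3G4R"}

    def test_round_trip_lossless(self, tmp_path):
        table = im.load_table2_fixture()
        path = tmp_path / "table.tsv"
        ma.write_table(table, path)
        back = ma.read_table(path)
        pd.testing.assert_frame_equal(back, table)

    def test_corrupted_fixture_detected(self, monkeypatch):
        monkeypatch.setattr(ma, "_FIXTURE_SHA256", "0" * 64)
        with pytest.raises(ValueError, match="corrupt"):
            im.load_table2_fixture()
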