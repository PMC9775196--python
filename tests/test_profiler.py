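"""Alert matching and the two-phase sequential classification workflow."""

import pytest

from aquaprof.profiler import match_alert, profile_compound, profile_inventory, results_to_frame

from conftest import brute_force_alert_ids


class TestMatchAlert:
    def test_michael_acceptor_matches_methyl_acrylate(self, core_kb, std):
        alert = core_kb.alerts["2.1.1-SA01"]
        m = match_alert(std("C=CC(=O)OC"), alert, core_kb)
        assert m is not None
        assert m.subgroup_id == "2.1.1" and m.domain_name == "reactive"
        assert len(m.matched_atom_indices) > 0

    def test_ethane_matches_nothing_electrophilic(self, core_kb, std):
        alert = core_kb.alerts["2.1.1-SA01"]
        assert match_alert(std("CC"), alert, core_kb) is None

    def test_sulfonylurea_matches_als_form_a(self, core_kb, std):
        alert = core_kb.alerts["3.3.1-SA01"]
        m = match_alert(std("O=C(Nc1ncccn1)NS(=O)(=O)c1ccccc1"), alert, core_kb)
        assert m is not None and m.subgroup_id == "3.3.1"

    def test_stepwise_sequence_requires_all_patterns(self, core_kb, std):
        # quaternary ammonium surfactant needs both the charged nitrogen and
        # the C8 chain; tetramethylammonium has only the former
        alert = core_kb.alerts["1.2.1-SA04"]
        assert match_alert(std("C[N+](C)(C)C"), alert, core_kb) is None
        assert match_alert(std("CCCCCCCCCC[N+](C)(C)C"), alert, core_kb) is not None

    def test_exclusion_vetoes_match(self, core_kb, std):
        # phenol carries a carbonyl exclusion: salicylic acid is vetoed
        alert = core_kb.alerts["1.2.1-SA01"]
        assert match_alert(std("Oc1ccccc1"), alert, core_kb) is not None
        assert match_alert(std("OC(=O)c1ccccc1O"), alert, core_kb) is None

    def test_lineage_is_consistent(self, core_kb, std):
        m = match_alert(std("CNC(=O)Oc1cccc2ccccc12"), core_kb.alerts["3.1.1-SA02"], core_kb)
        assert m.subgroup_id.startswith(m.group_id)
        assert m.group_id.startswith(str(m.domain_id))
        assert core_kb.mies[m.mie_id].subgroup_id == m.subgroup_id
        assert m.taxa == ("Metazoa",)


class TestProfileCompound:
    def test_imidazolinone_herbicide_single_specific_match(self, core_kb, std):
        r = profile_compound(std("CC(C)C1(C)N=C(c2ncccc2C(=O)O)NC1=O"), core_kb)
        assert r.status == "classified" and r.phase == 1
        assert [m.subgroup_id for m in r.matches] == ["3.3.1"]
        assert r.matches[0].domain_name == "specific"

    def test_hexane_is_nonpolar_narcotic_in_phase_two(self, core_kb, std):
        r = profile_compound(std("CCCCCC"), core_kb)
        assert r.phase == 2
        assert r.alert_ids == {"1.1.1-SA01"}
        assert all(m.group_id == "1.1" for m in r.matches)

    def test_methyl_acrylate_never_reaches_nonpolar_narcosis(self, core_kb, std):
        r = profile_compound(std("C=CC(=O)OC"), core_kb)
        assert r.phase == 1
        assert any(m.domain_id == 2 for m in r.matches)
        assert not any(m.group_id == "1.1" for m in r.matches)
        assert r.alert_ids == brute_force_alert_ids(r.parent_smiles, core_kb)

    def test_totally_inert_molecule_is_unclassified(self, core_kb, std):
        r = profile_compound(std("OC(=O)CCC(=O)O"), core_kb)  # succinic acid
        assert r.status == "unclassified" and r.phase is None and not r.matches

    def test_multi_label_synthetic_molecule_accrues_both_matches(self, core_kb, std):
        # engineered bifunctional: acrylate ester (Michael acceptor, 2.1.1)
        # tethered to an epoxide (hard electrophile, 2.1.2)
        r = profile_compound(std("C=CC(=O)OCC1CO1"), core_kb)
        assert {"2.1.1-SA01", "2.1.2-SA01"} <= r.alert_ids
        assert r.phase == 1

    def test_compound_with_only_vetoed_alerts_falls_through_to_phase_two(
        self, core_kb, std
    ):
        # anisole: ether pattern embeds but the aromatic-carbon exclusion
        # vetoes the ether rule, and nothing else fires
        r = profile_compound(std("COc1ccccc1"), core_kb)
        assert r.status == "unclassified"


class TestProfileInventory:
    def test_empty(self, core_kb):
        assert profile_inventory([], core_kb) == []

    def test_batch_equals_individual(self, core_kb, std):
        compounds = [std("CCCCCC", "a"), std("C=CC(=O)OC", "b")]
        batch = profile_inventory(compounds, core_kb)
        solo = [profile_compound(c, core_kb) for c in compounds]
        assert batch == solo

    def test_output_order_matches_input(self, core_kb, std):
        compounds = [std(s, f"r{i}") for i, s in enumerate(["CCO", "CCCCCC", "Nc1ccccc1"])]
        results = profile_inventory(compounds, core_kb)
        assert [r.record_id for r in results] == ["r0", "r1", "r2"]


class TestSequentialRuleProperties:
    def test_mutual_exclusion_over_randomized_fixture_profiles(
        self, core_kb, fixture_inventory
    ):
        """No result may combine a nonpolar-narcosis match with any other."""
        from aquaprof.prep import preprocess_inventory

        records, _ = fixture_inventory
        compounds, _ = preprocess_inventory(records)
        results = profile_inventory(compounds, core_kb)
        assert len(results) >= 100
        for r in results:
            groups = {m.group_id for m in r.matches}
            if "1.1" in groups:
                assert groups == {"1.1"}, (r.record_id, groups)
            if r.phase == 2:
                assert all(m.domain_id == 1 and m.group_id == "1.1" for m in r.matches)
            if r.phase == 1:
                assert "1.1" not in groups

    def test_lineage_monotonicity(self, core_kb, fixture_inventory):
        from aquaprof.prep import preprocess_inventory

        records, _ = fixture_inventory
        compounds, _ = preprocess_inventory(records)
        for r in profile_inventory(compounds, core_kb):
            n_dom = len({m.domain_id for m in r.matches})
            n_grp = len({m.group_id for m in r.matches})
            n_sub = len({m.subgroup_id for m in r.matches})
            assert n_dom <= n_grp <= n_sub <= len(r.matches)

    def test_oracle_equivalence_on_fixture_inventory(self, core_kb, fixture_inventory):
        """Profiler output equals brute-force evaluation + post-hoc phase rule."""
        from aquaprof.prep import preprocess_inventory

        records, _ = fixture_inventory
        compounds, _ = preprocess_inventory(records)
        for c, r in zip(compounds, profile_inventory(compounds, core_kb)):
            assert r.alert_ids == brute_force_alert_ids(c.parent_smiles, core_kb), c


class TestResultsFrame:
    def test_long_form_columns_and_unclassified_row(self, core_kb, std):
        results = profile_inventory([std("CCCCCC", "a"), std("OC(=O)CCC(=O)O", "b")], core_kb)
        frame = results_to_frame(results)
        assert list(frame.columns)[:4] == ["record_id", "parent_smiles", "status", "phase"]
        b_rows = frame[frame.record_id == "b"]
        assert len(b_rows) == 1 and b_rows.iloc[0]["alert_id"] == ""
        assert b_rows.iloc[0]["status"] == "unclassified"
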