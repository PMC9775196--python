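"""Knowledge-base loading, validation, summary and round-trip behaviour."""

import pytest
import yaml

from aquaprof.kb import (
    KBParseError,
    KBValidationError,
    build_kb,
    dump_kb,
    kb_summary,
    load_kb,
    validate_kb,
)

MINIMAL = {
    "metadata": {"name": "t", "version": "0"},
    "domains": [
        {"id": 1, "name": "narcosis"},
        {"id": 2, "name": "reactive"},
        {"id": 3, "name": "specific"},
    ],
    "groups": [{"id": "1.1", "name": "nonpolar narcosis", "domain_id": 1}],
    "subgroups": [{"id": "1.1.1", "name": "nonpolar", "group_id": "1.1"}],
    "mies": [{"id": "M1", "name": "baseline", "subgroup_id": "1.1.1"}],
    "alerts": [],
}


def write_kb(tmp_path, data, name="kb.yaml"):
    path = tmp_path / name
    path.write_text(yaml.safe_dump(data))
    return path


class TestLoading:
    def test_core_kb_has_three_domains(self, core_kb):
        assert len(core_kb.domains) == 3
        assert {d.name for d in core_kb.domains.values()} == {
            "narcosis",
            "reactive",
            "specific",
        }

    def test_empty_kb_is_valid_with_zero_alerts(self, tmp_path):
        kb = load_kb(write_kb(tmp_path, MINIMAL))
        assert len(kb.alerts) == 0
        assert kb_summary(kb).n_sa_total == 0
        assert validate_kb(kb).ok

    def test_dangling_mie_reference_names_offender(self, tmp_path):
        data = dict(MINIMAL)
        data["alerts"] = [
            {
                "id": "A1",
                "name": "x",
                "smarts_sequence": ["[CX4]"],
                "mie_id": "X9",
                "taxa": ["all taxa and species"],
            }
        ]
        with pytest.raises(KBValidationError, match="X9"):
            load_kb(write_kb(tmp_path, data))

    def test_invalid_smarts_names_alert(self, tmp_path):
        data = dict(MINIMAL)
        data["alerts"] = [
            {
                "id": "A1",
                "name": "x",
                "smarts_sequence": ["[[[not-smarts"],
                "mie_id": "M1",
                "taxa": ["all taxa and species"],
            }
        ]
        with pytest.raises(KBValidationError, match="A1"):
            load_kb(write_kb(tmp_path, data))

    def test_malformed_file_raises_parse_error(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("alerts: [unclosed")
        with pytest.raises(KBParseError):
            load_kb(path)

    def test_missing_top_level_key_raises(self, tmp_path):
        data = {k: v for k, v in MINIMAL.items() if k != "mies"}
        with pytest.raises(KBParseError, match="mies"):
            load_kb(write_kb(tmp_path, data))

    def test_json_kb_also_loads(self, tmp_path, core_kb):
        path = tmp_path / "kb.json"
        dump_kb(core_kb, path)
        kb2 = load_kb(path)
        assert kb2.alerts == core_kb.alerts

    def test_loading_is_order_independent(self, tmp_path, core_kb):
        data = core_kb.to_dict()
        data["alerts"] = list(reversed(data["alerts"]))
        data["mies"] = list(reversed(data["mies"]))
        kb2 = build_kb(data)
        assert set(kb2.alerts) == set(core_kb.alerts)
        assert kb_summary(kb2).per_subgroup.set_index("subgroup_id")["n_sa"].to_dict() == (
            kb_summary(core_kb).per_subgroup.set_index("subgroup_id")["n_sa"].to_dict()
        )


class TestRoundTrip:
    def test_serialize_reload_identity(self, tmp_path, core_kb):
        path = tmp_path / "rt.yaml"
        dump_kb(core_kb, path)
        kb2 = load_kb(path)
        assert kb2.domains == core_kb.domains
        assert kb2.groups == core_kb.groups
        assert kb2.subgroups == core_kb.subgroups
        assert kb2.mies == core_kb.mies
        assert kb2.alerts == core_kb.alerts


class TestValidation:
    def test_core_kb_self_validates(self, core_kb):
        report = validate_kb(core_kb)
        assert report.ok, report.to_frame()
        assert report.n_alerts_checked == len(core_kb.alerts)

    def test_failing_positive_example_is_reported(self, tmp_path):
        data = dict(MINIMAL)
        data["alerts"] = [
            {
                "id": "A1",
                "name": "alkane",
                "smarts_sequence": ["[CX4]"],
                "mie_id": "M1",
                "taxa": ["all taxa and species"],
                "positive_examples": ["c1ccccc1"],  # benzene has no sp3 carbon
            }
        ]
        report = validate_kb(load_kb(write_kb(tmp_path, data)))
        assert not report.ok
        assert any(
            i.entity_id == "A1" and i.kind == "positive_example_mismatch"
            for i in report.issues
        )

    def test_matching_negative_example_is_reported(self, tmp_path):
        data = dict(MINIMAL)
        data["alerts"] = [
            {
                "id": "A1",
                "name": "alkane",
                "smarts_sequence": ["[CX4]"],
                "mie_id": "M1",
                "taxa": ["all taxa and species"],
                "negative_examples": ["CC"],
            }
        ]
        report = validate_kb(load_kb(write_kb(tmp_path, data)))
        assert any(i.kind == "negative_example_match" for i in report.issues)

    def test_duplicate_alert_ids_are_reported(self, tmp_path):
        data = dict(MINIMAL)
        alert = {
            "id": "A1",
            "name": "x",
            "smarts_sequence": ["[CX4]"],
            "mie_id": "M1",
            "taxa": ["all taxa and species"],
        }
        data["alerts"] = [alert, dict(alert)]
        report = validate_kb(load_kb(write_kb(tmp_path, data)))
        assert any(i.kind == "duplicate_id" and "A1" in i.message for i in report.issues)

    def test_empty_taxa_is_reported(self, tmp_path):
        data = dict(MINIMAL)
        data["alerts"] = [
            {
                "id": "A1",
                "name": "x",
                "smarts_sequence": ["[CX4]"],
                "mie_id": "M1",
                "taxa": [],
            }
        ]
        report = validate_kb(load_kb(write_kb(tmp_path, data)))
        assert any(i.kind == "taxa_empty" for i in report.issues)


class TestSummary:
    def test_grand_total_matches_alert_count(self, core_kb):
        summary = kb_summary(core_kb)
        assert summary.n_sa_total == len(core_kb.alerts)
        assert summary.per_subgroup["n_sa"].sum() == summary.n_sa_total
        assert summary.per_domain["n_sa"].sum() == summary.n_sa_total

    def test_hierarchy_cardinalities_are_monotone(self, core_kb):
        summary = kb_summary(core_kb)
        assert summary.n_domains <= summary.n_groups <= summary.n_subgroups

    @pytest.mark.parametrize(
        "subgroup_id, n_mie, n_sa",
        [("3.3.1", 3, 6), ("2.2.1", 1, 0), ("1.1.1", 1, 6)],
    )
    def test_core_subgroup_counts(self, core_kb, subgroup_id, n_mie, n_sa):
        assert kb_summary(core_kb).subgroup_counts(subgroup_id) == (n_mie, n_sa)

    def test_format_hosts_large_alert_sets(self, core_kb):
        """The KB format must scale to the full published rule set size."""
        data = core_kb.to_dict()
        template = data["alerts"][0]
        extra = [
            {**template, "id": f"X-{i:03d}", "positive_examples": [], "negative_examples": []}
            for i in range(183 - len(data["alerts"]))
        ]
        data["alerts"] = data["alerts"] + extra
        big = build_kb(data)
        assert kb_summary(big).n_sa_total == 183
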