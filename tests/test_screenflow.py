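"""PICOS validation, prompt construction, verdict parsing and adjudication."""

import json

import pytest

from triscreen.records import ReferenceRecord
from triscreen.screenflow import (
    MockBackend,
    ResponseParseError,
    ScreeningDecision,
    adjudicate,
    build_prompt,
    parse_decisions,
    validate_criteria,
)
from triscreen.screenflow.backends import BackendProfile
from triscreen.screenflow.prompts import UNRESTRICTED


class TestValidateCriteria:
    def test_all_five_empty_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            validate_criteria()

    def test_single_element_flags_other_four_unspecified(self):
        c = validate_criteria(population="adults with cirrhosis")
        assert c.unspecified_flags == {
            "intervention", "comparison", "outcome", "study_design",
        }

    def test_all_five_set_no_flags(self):
        c = validate_criteria("p", "i", "c", "o", "s")
        assert c.unspecified_flags == frozenset()

    def test_whitespace_only_counts_as_empty(self):
        c = validate_criteria(population="pop", outcome="   ")
        assert "outcome" in c.unspecified_flags


def _records(n):
    return [
        ReferenceRecord(f"r{i}", "db", title=f"Title {i}", abstract=f"Abstract {i}.")
        for i in range(1, n + 1)
    ]


class TestBuildPrompt:
    def test_reviewer_prompt_contains_each_record_id_exactly_once(self, criteria):
        batch = _records(3)
        prompt = build_prompt("reviewer", criteria, batch)
        for rec in batch:
            assert prompt.count(f"### RECORD {rec.record_id}\n") == 1
        assert "PRIOR" not in prompt

    def test_unspecified_elements_rendered_as_not_restricted(self, criteria):
        prompt = build_prompt("reviewer", criteria, _records(1))
        assert f"- Outcome: {UNRESTRICTED}" in prompt
        assert "- Population: hepatocellular carcinoma cirrhosis" in prompt

    def test_critic_prompt_carries_reviewer_verdict_and_reason(self, criteria):
        batch = _records(1)
        prior = {"r1": ScreeningDecision("r1", "reviewer", "include", "matches criteria")}
        prompt = build_prompt("critic", criteria, batch, prior)
        assert "reviewer=include" in prompt
        assert "matches criteria" in prompt

    def test_arbitrator_prompt_shows_both_conflicting_verdicts(self, criteria):
        batch = _records(1)
        prior = {
            "r1": (
                ScreeningDecision("r1", "reviewer", "include", "a"),
                ScreeningDecision("r1", "critic", "exclude", "b"),
            )
        }
        prompt = build_prompt("arbitrator", criteria, batch, prior)
        assert "reviewer=include critic=exclude" in prompt

    def test_prior_required_for_critic_and_arbitrator(self, criteria):
        with pytest.raises(ValueError, match="prior"):
            build_prompt("critic", criteria, _records(1))

    def test_batch_over_max_size_rejected(self, criteria):
        with pytest.raises(ValueError, match="exceeds"):
            build_prompt("reviewer", criteria, _records(5), max_batch_size=3)

    def test_empty_batch_rejected(self, criteria):
        with pytest.raises(ValueError, match="non-empty"):
            build_prompt("reviewer", criteria, [])


class TestParseDecisions:
    def test_well_formed_structured_response(self):
        response = json.dumps([
            {"id": "r1", "verdict": "include", "reason": "fits"},
            {"id": "r2", "verdict": "exclude", "reason": "wrong design"},
        ])
        decisions = parse_decisions(response, ["r1", "r2"])
        assert [(d.record_id, d.verdict) for d in decisions] == [
            ("r1", "include"), ("r2", "exclude"),
        ]

    def test_missing_id_raises_naming_it(self):
        response = json.dumps([{"id": "r1", "verdict": "include", "reason": ""}])
        with pytest.raises(ResponseParseError, match="r2") as err:
            parse_decisions(response, ["r1", "r2"])
        assert err.value.missing_ids == ["r2"]

    def test_case_and_punctuation_noise_normalized(self):
        response = json.dumps([{"id": "r1", "verdict": "INCLUDE.", "reason": ""}])
        assert parse_decisions(response, ["r1"])[0].verdict == "include"

    def test_lenient_line_fallback_when_json_broken(self):
        response = "r1: include because it matches\nr2 -> EXCLUDE (wrong population)"
        decisions = parse_decisions(response, ["r1", "r2"])
        assert [d.verdict for d in decisions] == ["include", "exclude"]

    def test_decisions_returned_in_expected_id_order(self):
        response = json.dumps([
            {"id": "r2", "verdict": "exclude", "reason": ""},
            {"id": "r1", "verdict": "include", "reason": ""},
        ])
        assert [d.record_id for d in parse_decisions(response, ["r1", "r2"])] == ["r1", "r2"]


class TestAdjudicate:
    def _decision(self, role, verdict, rid="r1"):
        return ScreeningDecision(rid, role, verdict, f"{role} reasoning")

    def _arb_supplier(self, verdict):
        calls = []
        def supplier(rid):
            calls.append(rid)
            return ScreeningDecision(rid, "arbitrator", verdict, "arb reasoning")
        supplier.calls = calls
        return supplier

    def test_agreement_skips_arbitrator(self):
        supplier = self._arb_supplier("exclude")
        result = adjudicate(
            self._decision("reviewer", "include"), self._decision("critic", "include"), supplier
        )
        assert not result.conflict
        assert result.final_verdict == "include"
        assert result.arbitrator_verdict is None
        assert supplier.calls == []

    def test_conflict_resolved_by_arbitrator(self):
        supplier = self._arb_supplier("exclude")
        result = adjudicate(
            self._decision("reviewer", "include"), self._decision("critic", "exclude"), supplier
        )
        assert result.conflict
        assert result.final_verdict == "exclude"
        assert supplier.calls == ["r1"]

    def test_shared_exclude_final_exclude(self):
        result = adjudicate(
            self._decision("reviewer", "exclude"), self._decision("critic", "exclude"),
            self._arb_supplier("include"),
        )
        assert result.final_verdict == "exclude" and not result.conflict

    def test_mismatched_record_ids_rejected(self):
        with pytest.raises(ValueError, match="mismatched"):
            adjudicate(
                self._decision("reviewer", "include", "r1"),
                self._decision("critic", "include", "r2"),
                self._arb_supplier("include"),
            )


class TestMockBackend:
    def test_keyword_hit_includes_and_miss_excludes(self, criteria, profiles):
        batch = [
            ReferenceRecord("hit", "db", title="Hepatic resection outcomes",
                            abstract="Patients with cirrhosis after resection."),
            ReferenceRecord("miss", "db", title="Asthma education survey",
                            abstract="Telehealth nursing registry."),
        ]
        prompt = build_prompt("reviewer", criteria, batch)
        response, usage = MockBackend(threshold=1).complete(profiles["reviewer"], prompt)
        verdicts = {d["id"]: d["verdict"] for d in json.loads(response)}
        assert verdicts == {"hit": "include", "miss": "exclude"}
        assert usage.prompt_tokens > 0 and usage.completion_tokens > 0

    def test_byte_identical_response_for_identical_prompt(self, criteria, profiles):
        prompt = build_prompt("reviewer", criteria, _records(4))
        backend = MockBackend()
        r1, u1 = backend.complete(profiles["reviewer"], prompt)
        r2, u2 = backend.complete(profiles["reviewer"], prompt)
        assert r1 == r2 and u1 == u2

    def test_adding_matching_keyword_never_flips_include_to_exclude(self, profiles):
        rec = ReferenceRecord("r1", "db", title="Cirrhosis cohort",
                              abstract="Resection and ablation outcomes.")
        base = validate_criteria(population="cirrhosis")
        wider = validate_criteria(population="cirrhosis", intervention="ablation")
        backend = MockBackend(threshold=1)
        for threshold_criteria in (base, wider):
            prompt = build_prompt("reviewer", threshold_criteria, [rec])
            response, _ = backend.complete(profiles["reviewer"], prompt)
            assert json.loads(response)[0]["verdict"] == "include"

    def test_unspecified_elements_contribute_no_keywords(self, profiles):
        # the "not restricted" rendering must not leak words into matching
        rec = ReferenceRecord("r1", "db", title="restricted element wording",
                              abstract="do not exclude on this element")
        c = validate_criteria(population="cirrhosis")
        prompt = build_prompt("reviewer", c, [rec])
        response, _ = MockBackend(threshold=1).complete(profiles["reviewer"], prompt)
        assert json.loads(response)[0]["verdict"] == "exclude"
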