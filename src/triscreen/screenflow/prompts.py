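"""Prompt construction and verdict parsing.

All three roles share one prompt layout: a role preamble, the PICOS block
(unspecified elements rendered as "not restricted — do not exclude on this
element"), one block per record carrying its stable id, title, abstract and —
for the critic and arbitrator — the prior verdict(s), and a closing
instruction to answer as a JSON array of ``{"id", "verdict", "reason"}``
objects.  ``parse_decisions`` tries the structured JSON form first and falls
back to a lenient line-oriented pattern before raising a retryable error.
"""

from __future__ import annotations

import json
import re
from typing import Iterable, Mapping, Sequence, TYPE_CHECKING

from triscreen.records import ReferenceRecord
from triscreen.screenflow.criteria import PICOSCriteria, PICOS_ELEMENTS

if TYPE_CHECKING:  # pragma: no cover
    from triscreen.screenflow.engine import ScreeningDecision

__all__ = ["build_prompt", "parse_decisions", "ResponseParseError", "ROLES"]

ROLES = ("reviewer", "critic", "arbitrator")

UNRESTRICTED = "not restricted — do not exclude on this element"

_PREAMBLES = {
    "reviewer": (
        "You are the initial reviewer in a systematic-review title/abstract "
        "screening task. Judge each record below strictly against the PICOS "
        "criteria and decide include or exclude, with a short reason."
    ),
    "critic": (
        "You are the critic in a systematic-review title/abstract screening "
        "task. The initial reviewer's verdict for each record is shown. "
        "Re-evaluate every record independently against the same PICOS "
        "criteria and give your own include/exclude verdict with a short "
        "reason; do not defer to the reviewer."
    ),
    "arbitrator": (
        "You are the arbitrator in a systematic-review title/abstract "
        "screening task. The reviewer and the critic disagreed on every "
        "record below; both verdicts are shown. Re-analyze each record "
        "against the PICOS criteria and make the final include/exclude "
        "determination with a short reason."
    ),
}

_ELEMENT_LABELS = {
    "population": "Population",
    "intervention": "Intervention",
    "comparison": "Comparison",
    "outcome": "Outcome",
    "study_design": "Study design",
}

_RESPONSE_INSTRUCTION = (
    'Respond with a JSON array only, one object per record, in the form '
    '[{"id": "<record id>", "verdict": "include" | "exclude", "reason": "<short reason>"}]. '
    "Every record id above must appear exactly once."
)


def render_picos_block(criteria: PICOSCriteria) -> str:
    lines = ["PICOS criteria:"]
    for element in PICOS_ELEMENTS:
        label = _ELEMENT_LABELS[element]
        if element in criteria.unspecified_flags:
            lines.append(f"- {label}: {UNRESTRICTED}")
        else:
            lines.append(f"- {label}: {criteria.element(element)}")
    return "\n".join(lines)


def build_prompt(
    role: str,
    criteria: PICOSCriteria,
    batch: Sequence[ReferenceRecord],
    prior: Mapping[str, "ScreeningDecision | Sequence[ScreeningDecision]"] | None = None,
    *,
    max_batch_size: int | None = None,
    include_prior_reasoning: bool = True,
) -> str:
    """Render the prompt for one role over one batch of records.

    ``prior`` maps record_id to the reviewer's decision (critic role) or to
    the (reviewer, critic) decision pair (arbitrator role); it is required
    for those roles.  By default the critic sees the reviewer's reasoning
    while the arbitrator sees only the two conflicting verdicts.
    """
    if role not in ROLES:
        raise ValueError(f"unknown role {role!r}; expected one of {ROLES}")
    if not batch:
        raise ValueError("batch must be non-empty")
    if max_batch_size is not None and len(batch) > max_batch_size:
        raise ValueError(
            f"batch of {len(batch)} records exceeds configured maximum {max_batch_size}"
        )
    if role in ("critic", "arbitrator") and prior is None:
        raise ValueError(f"role {role!r} requires prior decisions")

    parts = [_PREAMBLES[role], "", render_picos_block(criteria), "", "Records:"]
    for rec in batch:
        parts.append(f"### RECORD {rec.record_id}")
        parts.append(f"TITLE: {_oneline(rec.title)}")
        parts.append(f"ABSTRACT: {_oneline(rec.abstract)}")
        if role == "critic":
            decision = prior[rec.record_id]  # type: ignore[index]
            line = f"PRIOR: reviewer={decision.verdict}"
            if include_prior_reasoning and decision.reasoning:
                line += f" reason={_oneline(decision.reasoning)}"
            parts.append(line)
        elif role == "arbitrator":
            pair = prior[rec.record_id]  # type: ignore[index]
            reviewer, critic = pair  # type: ignore[misc]
            parts.append(f"PRIOR: reviewer={reviewer.verdict} critic={critic.verdict}")
        parts.append("### END")
    parts.append("")
    parts.append(_RESPONSE_INSTRUCTION)
    return "\n".join(parts)


def _oneline(text: str) -> str:
    return " ".join(text.split())


class ResponseParseError(ValueError):
    """The backend response could not be mapped onto the expected record ids.

    Carries the offending ids so the caller can retry the batch.
    """

    def __init__(self, message: str, missing_ids: Sequence[str]):
        super().__init__(message)
        self.missing_ids = list(missing_ids)


_VERDICT_RE = re.compile(r"^(include|exclude)", re.IGNORECASE)


def _normalize_verdict(raw: str) -> str | None:
    m = _VERDICT_RE.match(raw.strip().strip('".,!:;'))
    return m.group(1).lower() if m else None


def _extract_json_array(text: str) -> list | None:
    decoder = json.JSONDecoder()
    for start in range(len(text)):
        if text[start] == "[":
            try:
                value, _ = decoder.raw_decode(text, start)
            except json.JSONDecodeError:
                continue
            if isinstance(value, list):
                return value
    return None


def parse_decisions(
    response: str, expected_ids: Iterable[str], role: str = "reviewer"
) -> "list[ScreeningDecision]":
    """Parse one backend response into one decision per expected record id.

    A structured JSON-array parse is attempted first; records it does not
    cover are retried with a lenient per-line pattern (the id followed by an
    include/exclude token).  Any record still missing a usable verdict
    raises :class:`ResponseParseError` naming the ids at fault.
    """
    from triscreen.screenflow.engine import ScreeningDecision

    expected = list(expected_ids)
    found: dict[str, tuple[str, str]] = {}

    array = _extract_json_array(response)
    if array is not None:
        for item in array:
            if not isinstance(item, dict):
                continue
            rid = str(item.get("id", ""))
            verdict = _normalize_verdict(str(item.get("verdict", "")))
            if rid in expected and verdict and rid not in found:
                found[rid] = (verdict, str(item.get("reason", "")))

    missing = [rid for rid in expected if rid not in found]
    if missing:
        for line in response.splitlines():
            for rid in list(missing):
                if rid in line:
                    m = re.search(r"\b(include|exclude)\b", line, re.IGNORECASE)
                    if m:
                        found[rid] = (m.group(1).lower(), line.strip())
                        missing.remove(rid)
        if missing:
            raise ResponseParseError(
                f"response is missing a parseable verdict for record ids: {missing}",
                missing_ids=missing,
            )

    return [
        ScreeningDecision(
            record_id=rid, role=role, verdict=found[rid][0], reasoning=found[rid][1]
        )
        for rid in expected
    ]
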