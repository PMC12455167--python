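"""PICOS eligibility criteria handling.

A screening task must specify at least one non-empty PICOS element
(Population, Intervention, Comparison, Outcome, Study design).  Elements
left empty are flagged as *unspecified*: the prompts render them as
"not restricted" and explicitly forbid excluding a record on that element,
widening the effective search scope rather than silently narrowing it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["PICOSCriteria", "validate_criteria", "PICOS_ELEMENTS"]

PICOS_ELEMENTS = ("population", "intervention", "comparison", "outcome", "study_design")


@dataclass(frozen=True)
class PICOSCriteria:
    population: str = ""
    intervention: str = ""
    comparison: str = ""
    outcome: str = ""
    study_design: str = ""
    unspecified_flags: frozenset[str] = field(default_factory=frozenset)

    def element(self, name: str) -> str:
        if name not in PICOS_ELEMENTS:
            raise KeyError(name)
        return getattr(self, name)

    def specified(self) -> list[str]:
        return [e for e in PICOS_ELEMENTS if e not in self.unspecified_flags]


def validate_criteria(
    population: str | None = None,
    intervention: str | None = None,
    comparison: str | None = None,
    outcome: str | None = None,
    study_design: str | None = None,
) -> PICOSCriteria:
    """Build validated criteria from five optional texts.

    Raises ``ValueError`` when all five elements are empty — a screening task
    must contain at least one non-empty PICOS element.
    """
    values = {
        "population": (population or "").strip(),
        "intervention": (intervention or "").strip(),
        "comparison": (comparison or "").strip(),
        "outcome": (outcome or "").strip(),
        "study_design": (study_design or "").strip(),
    }
    unspecified = frozenset(name for name, text in values.items() if not text)
    if len(unspecified) == len(PICOS_ELEMENTS):
        raise ValueError(
            "invalid criteria: a screening task must contain at least one "
            "non-empty PICOS element (all five are empty)"
        )
    return PICOSCriteria(unspecified_flags=unspecified, **values)
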