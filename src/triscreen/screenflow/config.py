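"""Run configuration: PICOS block, role→profile bindings and pipeline knobs.

Config files are YAML (or JSON, a YAML subset), e.g.::

    picos:
      population: adults with hepatocellular carcinoma
      intervention: laparoscopic resection
      study_design: randomized controlled trial
    roles:
      reviewer:   {model_name: model-a, model_kind: general-purpose,
                   input_price_per_mtok: 0.11, output_price_per_mtok: 0.28}
      critic:     {model_name: model-b}
      arbitrator: {model_name: model-c, model_kind: reasoning-optimized}
    batch_size: 10
    max_retries: 2
    mock: {threshold: 1}
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from triscreen.screenflow.backends import BackendProfile, MockBackend
from triscreen.screenflow.criteria import PICOSCriteria, validate_criteria
from triscreen.screenflow.prompts import ROLES

__all__ = ["ScreenConfig", "load_config"]


@dataclass
class ScreenConfig:
    criteria: PICOSCriteria
    profiles: dict[str, BackendProfile]
    batch_size: int = 10
    max_retries: int = 2
    critic_sees_reasoning: bool = True
    filter_blank_abstracts: bool = True
    mock_threshold: int = 1
    base_url: str = ""
    api_key: str = ""

    def mock_backend(self) -> MockBackend:
        return MockBackend(threshold=self.mock_threshold)


def load_config(path: str | Path) -> ScreenConfig:
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    picos = raw.get("picos") or {}
    criteria = validate_criteria(
        population=picos.get("population"),
        intervention=picos.get("intervention"),
        comparison=picos.get("comparison"),
        outcome=picos.get("outcome"),
        study_design=picos.get("study_design"),
    )
    roles_raw = raw.get("roles") or {}
    profiles: dict[str, BackendProfile] = {}
    for role in ROLES:
        spec = dict(roles_raw.get(role) or {})
        spec.setdefault("model_name", f"mock-{role}")
        profiles[role] = BackendProfile(role=role, **spec)
    mock = raw.get("mock") or {}
    return ScreenConfig(
        criteria=criteria,
        profiles=profiles,
        batch_size=int(raw.get("batch_size", 10)),
        max_retries=int(raw.get("max_retries", 2)),
        critic_sees_reasoning=bool(raw.get("critic_sees_reasoning", True)),
        filter_blank_abstracts=bool(raw.get("filter_blank_abstracts", True)),
        mock_threshold=int(mock.get("threshold", 1)),
        base_url=str(raw.get("base_url", "")),
        api_key=str(raw.get("api_key", "")),
    )
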