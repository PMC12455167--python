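"""Completion backends: role profiles, a deterministic offline mock, a
verdict-scripted backend for simulation studies, and a generic
OpenAI-compatible chat-completion HTTP adapter.

Backends implement one method, ``complete(profile, prompt) -> (text, Usage)``,
and must be stateless across calls (or explicitly seeded), so a screening
run is a pure function of its inputs whenever its backend is.
"""

from __future__ import annotations

import json
import math
import re
import urllib.request
from dataclasses import dataclass, field
from typing import Callable, Mapping, Protocol, runtime_checkable

from triscreen.screenflow.prompts import UNRESTRICTED

__all__ = [
    "Usage",
    "BackendProfile",
    "CompletionBackend",
    "MockBackend",
    "ScriptedBackend",
    "OpenAIChatBackend",
    "BackendError",
]


@dataclass(frozen=True)
class Usage:
    prompt_tokens: int = 0
    completion_tokens: int = 0

    def __post_init__(self) -> None:
        if self.prompt_tokens < 0 or self.completion_tokens < 0:
            raise ValueError("token counts must be non-negative")

    def __add__(self, other: "Usage") -> "Usage":
        return Usage(
            self.prompt_tokens + other.prompt_tokens,
            self.completion_tokens + other.completion_tokens,
        )

    @property
    def total_tokens(self) -> int:
        return self.prompt_tokens + self.completion_tokens


@dataclass(frozen=True)
class BackendProfile:
    """Binding of one screening role to one model and its pricing.

    Prices are per 1,000,000 tokens in an opaque currency.  The default
    temperature of 0 keeps runs reproducible.
    """

    role: str
    model_name: str
    model_kind: str = "general-purpose"  # or "reasoning-optimized"
    hyperparameters: Mapping[str, object] = field(
        default_factory=lambda: {"temperature": 0.0, "max_tokens": 4096}
    )
    input_price_per_mtok: float = 0.0
    output_price_per_mtok: float = 0.0
    currency: str = "USD"

    def __post_init__(self) -> None:
        if self.input_price_per_mtok < 0 or self.output_price_per_mtok < 0:
            raise ValueError("prices must be non-negative")


@runtime_checkable
class CompletionBackend(Protocol):
    def complete(self, profile: BackendProfile, prompt: str) -> tuple[str, Usage]:
        ...  # pragma: no cover


class BackendError(RuntimeError):
    """The backend failed to produce a response."""


def _heuristic_tokens(text: str) -> int:
    return math.ceil(len(text) / 4)


_RECORD_BLOCK_RE = re.compile(
    r"### RECORD (?P<id>\S+)\n"
    r"TITLE: (?P<title>[^\n]*)\n"
    r"ABSTRACT: (?P<abstract>[^\n]*)\n"
    r"(?:PRIOR: (?P<prior>[^\n]*)\n)?"
    r"### END"
)

_PICOS_LINE_RE = re.compile(r"^- (?:Population|Intervention|Comparison|Outcome|Study design): (.*)$")

_WORD_RE = re.compile(r"[a-z0-9]{4,}")


class MockBackend:
    """Deterministic offline completion backend.

    Reads the PICOS block and the record blocks straight out of the prompt;
    a record is voted *include* when at least ``threshold`` distinct
    criteria keywords (word tokens of 4+ characters from the specified PICOS
    elements) occur in its title+abstract, else *exclude*.  Identical prompt
    in, byte-identical response out.  Adding a criteria keyword that a
    record's text contains can only raise that record's match count, so it
    can never flip the record from include to exclude.
    """

    def __init__(self, threshold: int = 1):
        if threshold < 1:
            raise ValueError("threshold must be >= 1")
        self.threshold = threshold

    def complete(self, profile: BackendProfile, prompt: str) -> tuple[str, Usage]:
        keywords = self._criteria_keywords(prompt)
        items = []
        for m in _RECORD_BLOCK_RE.finditer(prompt):
            text = f"{m.group('title')} {m.group('abstract')}".casefold()
            words = set(_WORD_RE.findall(text))
            hits = len(keywords & words)
            verdict = "include" if hits >= self.threshold else "exclude"
            items.append(
                {
                    "id": m.group("id"),
                    "verdict": verdict,
                    "reason": f"matched {hits} criteria keyword(s); threshold {self.threshold}",
                }
            )
        response = json.dumps(items)
        usage = Usage(_heuristic_tokens(prompt), _heuristic_tokens(response))
        return response, usage

    @staticmethod
    def _criteria_keywords(prompt: str) -> set[str]:
        keywords: set[str] = set()
        for line in prompt.splitlines():
            m = _PICOS_LINE_RE.match(line)
            if m and m.group(1) != UNRESTRICTED:
                keywords.update(_WORD_RE.findall(m.group(1).casefold()))
        return keywords


class ScriptedBackend:
    """Backend that answers from a precomputed per-role verdict table.

    Used to drive the pipeline with simulated reviewer/critic/arbitrator
    error models (see :mod:`triscreen.synthgen`): the verdict for each
    record id is looked up in the table for the profile's role.
    """

    def __init__(self, verdicts_by_role: Mapping[str, Mapping[str, str]]):
        self.verdicts_by_role = {r: dict(v) for r, v in verdicts_by_role.items()}

    def complete(self, profile: BackendProfile, prompt: str) -> tuple[str, Usage]:
        table = self.verdicts_by_role[profile.role]
        items = []
        for m in _RECORD_BLOCK_RE.finditer(prompt):
            rid = m.group("id")
            items.append(
                {"id": rid, "verdict": table[rid], "reason": "scripted verdict"}
            )
        response = json.dumps(items)
        return response, Usage(_heuristic_tokens(prompt), _heuristic_tokens(response))


class OpenAIChatBackend:
    """Generic chat-completion HTTP adapter (OpenAI-compatible wire shape).

    ``transport`` may be injected for testing: a callable taking the request
    payload dict and returning the parsed response dict.  The default
    transport POSTs ``{base_url}/chat/completions``.
    """

    def __init__(
        self,
        base_url: str,
        api_key: str = "",
        timeout: float = 120.0,
        transport: Callable[[dict], dict] | None = None,
    ):
        self.base_url = base_url.rstrip("/")
        self.api_key = api_key
        self.timeout = timeout
        self.transport = transport or self._http_transport

    def complete(self, profile: BackendProfile, prompt: str) -> tuple[str, Usage]:
        payload: dict = {
            "model": profile.model_name,
            "messages": [{"role": "user", "content": prompt}],
        }
        for key in ("temperature", "max_tokens", "top_p"):
            if key in profile.hyperparameters:
                payload[key] = profile.hyperparameters[key]
        try:
            data = self.transport(payload)
            text = data["choices"][0]["message"]["content"]
        except Exception as exc:  # noqa: BLE001 — wrap any transport failure
            raise BackendError(f"chat-completion request failed: {exc}") from exc
        usage_raw = data.get("usage") or {}
        usage = Usage(
            int(usage_raw.get("prompt_tokens", _heuristic_tokens(prompt))),
            int(usage_raw.get("completion_tokens", _heuristic_tokens(text))),
        )
        return text, usage

    def _http_transport(self, payload: dict) -> dict:  # pragma: no cover — network
        req = urllib.request.Request(
            f"{self.base_url}/chat/completions",
            data=json.dumps(payload).encode("utf-8"),
            headers={
                "Content-Type": "application/json",
                **({"Authorization": f"Bearer {self.api_key}"} if self.api_key else {}),
            },
            method="POST",
        )
        with urllib.request.urlopen(req, timeout=self.timeout) as resp:
            return json.loads(resp.read().decode("utf-8"))
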