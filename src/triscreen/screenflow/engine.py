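"""Orchestration of the three-role screening pipeline.

``screen_corpus`` batches the corpus, runs the reviewer over every batch,
runs the critic over the same batches with the reviewer's verdicts attached,
collects the records on which the two disagree, and sends only those to the
arbitrator.  The final verdict is the shared verdict when the first two
roles agree and the arbitrator's determination otherwise, so arbitrator
token usage is exactly zero on a run with no disagreements.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import pandas as pd

from triscreen.records import Corpus, ReferenceRecord
from triscreen.screenflow.backends import (
    BackendError,
    BackendProfile,
    CompletionBackend,
    Usage,
)
from triscreen.screenflow.criteria import PICOSCriteria
from triscreen.screenflow.prompts import ResponseParseError, build_prompt, parse_decisions

__all__ = [
    "ScreeningDecision",
    "AdjudicationResult",
    "RunLog",
    "LogEntry",
    "ScreeningRun",
    "ScreeningError",
    "screen_batch",
    "adjudicate",
    "screen_corpus",
    "verdict_table",
]

VERDICTS = ("include", "exclude")


@dataclass
class ScreeningDecision:
    record_id: str
    role: str
    verdict: str
    reasoning: str = ""
    usage: Usage = field(default_factory=Usage)

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValueError(f"verdict must be one of {VERDICTS}, got {self.verdict!r}")


@dataclass
class AdjudicationResult:
    record_id: str
    reviewer_verdict: str
    critic_verdict: str
    conflict: bool
    final_verdict: str
    arbitrator_verdict: str | None = None
    reasonings: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.conflict != (self.reviewer_verdict != self.critic_verdict):
            raise ValueError("conflict flag inconsistent with reviewer/critic verdicts")
        if self.conflict:
            if self.arbitrator_verdict is None:
                raise ValueError("conflicting verdicts require an arbitrator verdict")
            if self.final_verdict != self.arbitrator_verdict:
                raise ValueError("final verdict must equal arbitrator verdict on conflict")
        else:
            if self.arbitrator_verdict is not None:
                raise ValueError("arbitrator verdict must be absent without conflict")
            if self.final_verdict != self.reviewer_verdict:
                raise ValueError("final verdict must equal the shared verdict")


@dataclass
class LogEntry:
    stage: str
    model_name: str
    start: float
    end: float
    n_records: int
    usage: Usage

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "model_name": self.model_name,
            "start": self.start,
            "end": self.end,
            "n_records": self.n_records,
            "prompt_tokens": self.usage.prompt_tokens,
            "completion_tokens": self.usage.completion_tokens,
        }


@dataclass
class RunLog:
    """Per-call log of stages, timestamps and token usage.

    This is the ledger consumed by :mod:`triscreen.costsim` for cost and
    runtime accounting.
    """

    entries: list[LogEntry] = field(default_factory=list)

    def record(self, stage: str, model_name: str, start: float, end: float,
               n_records: int, usage: Usage) -> None:
        self.entries.append(LogEntry(stage, model_name, start, end, n_records, usage))

    def usage_by_model(self) -> dict[str, Usage]:
        out: dict[str, Usage] = {}
        for e in self.entries:
            out[e.model_name] = out.get(e.model_name, Usage()) + e.usage
        return out

    def usage_by_stage(self) -> dict[str, Usage]:
        out: dict[str, Usage] = {}
        for e in self.entries:
            out[e.stage] = out.get(e.stage, Usage()) + e.usage
        return out

    def to_jsonl(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            for e in self.entries:
                fh.write(json.dumps(e.to_dict()) + "\n")

    @classmethod
    def from_jsonl(cls, path: str | Path) -> "RunLog":
        log = cls()
        with Path(path).open(encoding="utf-8") as fh:
            for line in fh:
                if not line.strip():
                    continue
                d = json.loads(line)
                log.record(
                    d["stage"], d["model_name"], d["start"], d["end"], d["n_records"],
                    Usage(d["prompt_tokens"], d["completion_tokens"]),
                )
        return log


@dataclass
class ScreeningRun:
    results: list[AdjudicationResult]
    log: RunLog

    def n_conflicts(self) -> int:
        return sum(r.conflict for r in self.results)


class ScreeningError(RuntimeError):
    """Backend or parse failure after exhausting retries.

    ``partial_results`` carries the decisions completed before the failure
    so a caller can checkpoint and resume.
    """

    def __init__(self, message: str, partial_results: Sequence[ScreeningDecision] = ()):
        super().__init__(message)
        self.partial_results = list(partial_results)


def _split_usage(usage: Usage, n: int) -> list[Usage]:
    """Attribute a call's usage to its n records; remainders go to the first."""
    p, c = usage.prompt_tokens, usage.completion_tokens
    base = [Usage(p // n, c // n) for _ in range(n)]
    base[0] = Usage(p // n + p % n, c // n + c % n)
    return base


def screen_batch(
    role: str,
    criteria: PICOSCriteria,
    batch: Sequence[ReferenceRecord],
    backend: CompletionBackend,
    profile: BackendProfile,
    prior: Mapping[str, object] | None = None,
    *,
    max_retries: int = 2,
    log: RunLog | None = None,
    include_prior_reasoning: bool = True,
) -> list[ScreeningDecision]:
    """Screen one batch under one role, retrying unparseable responses.

    Each retry resubmits the identical prompt; after ``max_retries``
    failures a :class:`ScreeningError` is raised.  Token usage for every
    attempt (including failed ones) is recorded in ``log``.
    """
    prompt = build_prompt(
        role, criteria, batch, prior, include_prior_reasoning=include_prior_reasoning
    )
    expected_ids = [r.record_id for r in batch]
    last_error: Exception | None = None
    for _attempt in range(max_retries + 1):
        start = time.time()
        try:
            response, usage = backend.complete(profile, prompt)
        except BackendError as exc:
            last_error = exc
            if log is not None:
                log.record(role, profile.model_name, start, time.time(), len(batch), Usage())
            continue
        if log is not None:
            log.record(role, profile.model_name, start, time.time(), len(batch), usage)
        try:
            decisions = parse_decisions(response, expected_ids, role)
        except ResponseParseError as exc:
            last_error = exc
            continue
        for decision, share in zip(decisions, _split_usage(usage, len(decisions))):
            decision.usage = share
        return decisions
    raise ScreeningError(
        f"{role} batch failed after {max_retries + 1} attempt(s): {last_error}",
    )


def adjudicate(
    reviewer: ScreeningDecision,
    critic: ScreeningDecision,
    arbitrator_supplier: Callable[[str], ScreeningDecision],
) -> AdjudicationResult:
    """Resolve one record's reviewer/critic pair into a final verdict.

    The arbitrator supplier is invoked only when the two verdicts conflict.
    """
    if reviewer.record_id != critic.record_id:
        raise ValueError(
            f"mismatched record ids: reviewer={reviewer.record_id!r} "
            f"critic={critic.record_id!r}"
        )
    reasonings = {"reviewer": reviewer.reasoning, "critic": critic.reasoning}
    if reviewer.verdict == critic.verdict:
        return AdjudicationResult(
            record_id=reviewer.record_id,
            reviewer_verdict=reviewer.verdict,
            critic_verdict=critic.verdict,
            conflict=False,
            final_verdict=reviewer.verdict,
            reasonings=reasonings,
        )
    arb = arbitrator_supplier(reviewer.record_id)
    reasonings["arbitrator"] = arb.reasoning
    return AdjudicationResult(
        record_id=reviewer.record_id,
        reviewer_verdict=reviewer.verdict,
        critic_verdict=critic.verdict,
        conflict=True,
        final_verdict=arb.verdict,
        arbitrator_verdict=arb.verdict,
        reasonings=reasonings,
    )


def _batches(records: Sequence[ReferenceRecord], size: int) -> list[list[ReferenceRecord]]:
    return [list(records[i : i + size]) for i in range(0, len(records), size)]


def screen_corpus(
    corpus: Corpus,
    criteria: PICOSCriteria,
    backends: CompletionBackend | Mapping[str, CompletionBackend],
    profiles: Mapping[str, BackendProfile],
    batch_size: int = 10,
    *,
    max_retries: int = 2,
    critic_sees_reasoning: bool = True,
) -> ScreeningRun:
    """Run the full reviewer → critic → arbitrator pipeline over a corpus.

    ``backends`` is either one backend shared by all roles or a mapping
    role → backend.  Returns exactly one :class:`AdjudicationResult` per
    record, in corpus order, plus the run log of timestamps and token usage.
    The number of arbitrator-screened records equals the number of
    reviewer/critic disagreements.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    for role in ("reviewer", "critic", "arbitrator"):
        if role not in profiles:
            raise ValueError(f"profiles must bind role {role!r}")

    def backend_for(role: str) -> CompletionBackend:
        if isinstance(backends, Mapping):
            return backends[role]
        return backends

    log = RunLog()
    records = list(corpus.records)
    if not records:
        return ScreeningRun(results=[], log=log)

    reviewer_decisions: dict[str, ScreeningDecision] = {}
    for batch in _batches(records, batch_size):
        for d in screen_batch(
            "reviewer", criteria, batch, backend_for("reviewer"),
            profiles["reviewer"], max_retries=max_retries, log=log,
        ):
            reviewer_decisions[d.record_id] = d

    critic_decisions: dict[str, ScreeningDecision] = {}
    for batch in _batches(records, batch_size):
        for d in screen_batch(
            "critic", criteria, batch, backend_for("critic"), profiles["critic"],
            prior=reviewer_decisions, max_retries=max_retries, log=log,
            include_prior_reasoning=critic_sees_reasoning,
        ):
            critic_decisions[d.record_id] = d

    conflict_records = [
        r for r in records
        if reviewer_decisions[r.record_id].verdict != critic_decisions[r.record_id].verdict
    ]
    arbitrator_decisions: dict[str, ScreeningDecision] = {}
    if conflict_records:
        prior_pairs = {
            r.record_id: (reviewer_decisions[r.record_id], critic_decisions[r.record_id])
            for r in conflict_records
        }
        for batch in _batches(conflict_records, batch_size):
            for d in screen_batch(
                "arbitrator", criteria, batch, backend_for("arbitrator"),
                profiles["arbitrator"], prior=prior_pairs,
                max_retries=max_retries, log=log,
            ):
                arbitrator_decisions[d.record_id] = d

    results = [
        adjudicate(
            reviewer_decisions[r.record_id],
            critic_decisions[r.record_id],
            lambda rid: arbitrator_decisions[rid],
        )
        for r in records
    ]
    return ScreeningRun(results=results, log=log)


def verdict_table(results: Sequence[AdjudicationResult]) -> pd.DataFrame:
    """Flatten adjudication results into the verdict table written by the CLI."""
    return pd.DataFrame(
        {
            "record_id": [r.record_id for r in results],
            "reviewer": [r.reviewer_verdict for r in results],
            "critic": [r.critic_verdict for r in results],
            "conflict": [r.conflict for r in results],
            "arbitrator": [r.arbitrator_verdict or "" for r in results],
            "final": [r.final_verdict for r in results],
        }
    )
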