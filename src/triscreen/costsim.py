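"""Token-cost simulation and runtime accounting.

Cloud platforms bill per token with separate input/output prices; billing
statements lag, so the cost of a screening run is estimated from the run
log's token ledger multiplied by a price table and reported per model, per
run and per 1000 records.  Runtime is summarized from the start/end
timestamps the pipeline logs per stage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from triscreen.screenflow.engine import RunLog
from triscreen.screenflow.backends import Usage

__all__ = [
    "PriceTable",
    "CostEstimate",
    "RuntimeSummary",
    "count_tokens",
    "estimate_cost",
    "summarize_runtime",
]


def count_tokens(text: str, reported: int | None = None) -> int:
    """Token count for a piece of text.

    Backend-reported usage is authoritative and passed through when
    available; otherwise the crude ceiling(characters / 4) heuristic is
    used (roughly one token per four characters of English text).
    """
    if reported is not None:
        if reported < 0:
            raise ValueError("reported token count must be non-negative")
        return reported
    return math.ceil(len(text) / 4)


@dataclass(frozen=True)
class ModelPrice:
    input_per_mtok: float
    output_per_mtok: float
    currency: str = "USD"

    def __post_init__(self) -> None:
        if self.input_per_mtok < 0 or self.output_per_mtok < 0:
            raise ValueError("prices must be non-negative")


@dataclass
class PriceTable:
    """Per-model input/output prices per 1,000,000 tokens.

    Prices are opaque numbers in a labelled currency; no conversion logic.
    """

    prices: dict[str, ModelPrice] = field(default_factory=dict)

    def __getitem__(self, model_name: str) -> ModelPrice:
        try:
            return self.prices[model_name]
        except KeyError:
            raise KeyError(
                f"model {model_name!r} has no entry in the price table"
            ) from None

    @classmethod
    def from_mapping(cls, raw: Mapping[str, Mapping[str, object]]) -> "PriceTable":
        table = cls()
        for model, spec in raw.items():
            table.prices[model] = ModelPrice(
                input_per_mtok=float(spec["input_per_mtok"]),
                output_per_mtok=float(spec["output_per_mtok"]),
                currency=str(spec.get("currency", "USD")),
            )
        return table

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PriceTable":
        return cls.from_mapping(yaml.safe_load(Path(path).read_text(encoding="utf-8")))


@dataclass
class CostEstimate:
    per_model: dict[str, dict[str, float]]  # model -> prompt/completion tokens, cost
    total: float
    currency: str
    n_records: int | None = None
    cost_per_1000_records: float | None = None


def estimate_cost(
    usage: RunLog | Mapping[str, Usage],
    prices: PriceTable,
    n_records: int | None = None,
) -> CostEstimate:
    """Cost of a run: Σ (prompt·input + completion·output) / 10⁶ per model.

    ``usage`` is a pipeline :class:`RunLog` or a plain model → Usage
    ledger.  Any model missing from the price table raises, naming it.
    """
    ledger = usage.usage_by_model() if isinstance(usage, RunLog) else dict(usage)
    per_model: dict[str, dict[str, float]] = {}
    total = 0.0
    currencies = set()
    for model, u in ledger.items():
        price = prices[model]
        currencies.add(price.currency)
        cost = (
            u.prompt_tokens * price.input_per_mtok
            + u.completion_tokens * price.output_per_mtok
        ) / 1_000_000
        per_model[model] = {
            "prompt_tokens": u.prompt_tokens,
            "completion_tokens": u.completion_tokens,
            "cost": cost,
        }
        total += cost
    if len(currencies) > 1:
        raise ValueError(f"mixed currencies in one estimate: {sorted(currencies)}")
    currency = currencies.pop() if currencies else "USD"
    per_1000 = None
    if n_records:
        per_1000 = total / n_records * 1000
    return CostEstimate(
        per_model=per_model,
        total=total,
        currency=currency,
        n_records=n_records,
        cost_per_1000_records=per_1000,
    )


@dataclass
class RuntimeSummary:
    per_stage: dict[str, float]  # stage -> elapsed seconds
    per_dataset: dict[str, float]  # dataset label -> elapsed seconds
    total: float
    mean: float
    sd: float
    n_records: int | None = None
    seconds_per_1000_records: float | None = None


def summarize_runtime(
    log: RunLog | Mapping[str, tuple[float, float]],
    datasets: Mapping[str, RunLog] | None = None,
) -> RuntimeSummary:
    """Elapsed-time summary from logged start/end timestamps.

    A single :class:`RunLog` yields per-stage elapsed times and one dataset
    labelled ``run``; pass ``datasets`` (label → RunLog) for the
    multi-dataset view with mean and SD across datasets.  An end timestamp
    before its start raises.
    """
    if datasets is not None:
        per_dataset = {}
        per_stage: dict[str, float] = {}
        n_records = 0
        for label, dlog in datasets.items():
            s = summarize_runtime(dlog)
            per_dataset[label] = s.total
            for stage, secs in s.per_stage.items():
                per_stage[stage] = per_stage.get(stage, 0.0) + secs
            n_records += s.n_records or 0
        values = np.array(list(per_dataset.values()))
        total = float(values.sum())
        return RuntimeSummary(
            per_stage=per_stage,
            per_dataset=per_dataset,
            total=total,
            mean=float(values.mean()),
            sd=float(values.std(ddof=1)) if len(values) > 1 else 0.0,
            n_records=n_records or None,
            seconds_per_1000_records=(total / n_records * 1000) if n_records else None,
        )

    if isinstance(log, RunLog):
        per_stage = {}
        n_records = 0
        for e in log.entries:
            if e.end < e.start:
                raise ValueError(
                    f"log entry for stage {e.stage!r} ends before it starts "
                    f"({e.end} < {e.start})"
                )
            per_stage[e.stage] = per_stage.get(e.stage, 0.0) + (e.end - e.start)
        # reviewer+critic see every record once; count records from the reviewer stage
        n_records = sum(e.n_records for e in log.entries if e.stage == "reviewer")
    else:
        per_stage = {}
        for stage, (start, end) in log.items():
            if end < start:
                raise ValueError(
                    f"stage {stage!r} ends before it starts ({end} < {start})"
                )
            per_stage[stage] = end - start
        n_records = 0
    total = float(sum(per_stage.values()))
    values = np.array(list(per_stage.values())) if per_stage else np.array([0.0])
    return RuntimeSummary(
        per_stage=per_stage,
        per_dataset={"run": total},
        total=total,
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)) if len(values) > 1 else 0.0,
        n_records=n_records or None,
        seconds_per_1000_records=(total / n_records * 1000) if n_records else None,
    )
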