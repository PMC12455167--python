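"""Seeded synthetic bibliographic corpora and simulated screening decisions.

The generator emulates the statistical shape of real screening corpora —
very low inclusion prevalence (defaults in the sub-4% regime typical of
treatment meta-analysis searches), cross-database duplicate records that
differ only in superficial formatting, and entries with blank abstracts —
while titles and abstracts are template-generated token sequences, not
natural language.  Gold-included records carry planted population and
intervention keywords; excluded records draw from decoy lexicons.  The same
seed always produces byte-identical files.

``simulate_role_decisions`` turns a gold label table into per-role verdict
tables under a sensitivity/specificity error model, which (via
``ScriptedBackend``) lets the full pipeline and the metric panel be
exercised end-to-end with no live model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from triscreen.records import Corpus, merge_corpora, parse_nbib, parse_ris
from triscreen.screenflow.criteria import PICOSCriteria, validate_criteria

__all__ = [
    "SyntheticCorpusSpec",
    "SyntheticCorpus",
    "RoleErrorModel",
    "generate_corpus",
    "simulate_role_decisions",
]

# Vocabulary pools.  Lexicon words mark gold-included records; decoy and
# filler words are disjoint from every lexicon so a keyword-matching screen
# can separate the classes.
_DEFAULT_LEXICONS: dict[str, list[str]] = {
    "population": ["hepatocellular", "carcinoma", "cirrhosis", "unresectable"],
    "intervention": ["resection", "ablation", "chemoembolization", "lenvatinib", "sorafenib"],
    "comparison": [],
    "outcome": ["survival", "recurrence"],
    "study_design": ["randomized", "controlled"],
}

_DECOY_WORDS = [
    "diabetes", "asthma", "migraine", "fracture", "dermatitis", "cataract",
    "insomnia", "scoliosis", "rhinitis", "gastritis", "tinnitus", "psoriasis",
    "vaccination", "telehealth", "nursing", "education", "screening", "registry",
]

_FILLER_WORDS = [
    "multicenter", "cohort", "retrospective", "prospective", "baseline",
    "follow", "adult", "elderly", "female", "male", "tertiary", "national",
]

_SURNAMES = [
    "Chen", "Wang", "Li", "Zhang", "Liu", "Garcia", "Smith", "Johnson",
    "Mueller", "Rossi", "Tanaka", "Kim", "Silva", "Novak", "Dubois", "Olsen",
]

_JOURNALS = [
    "Journal of Synthetic Hepatology",
    "Annals of Simulated Surgery",
    "Synthetic Oncology Reports",
    "Archives of Generated Medicine",
]


@dataclass
class SyntheticCorpusSpec:
    """Parameters of one synthetic corpus.

    Defaults mirror the screening regime the pipeline targets: 1000 unique
    records, 1% inclusion prevalence (the observed range in treatment
    meta-analysis corpora runs roughly 0.17%–3.9%), a 10% planted
    cross-database duplicate rate and 5% blank abstracts.
    """

    n_records: int = 1000
    prevalence: float = 0.01
    databases: tuple[str, ...] = ("pubmed", "cochrane")
    duplicate_rate: float = 0.10
    blank_abstract_rate: float = 0.05
    lexicons: dict[str, list[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in _DEFAULT_LEXICONS.items()}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")
        for name in ("prevalence", "duplicate_rate", "blank_abstract_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if len(self.databases) < 1:
            raise ValueError("need at least one database")

    def n_included(self) -> int:
        n = round(self.n_records * self.prevalence)
        if n < 1:
            warnings.warn(
                "prevalence × n_records < 1; forcing one gold-included record",
                UserWarning,
                stacklevel=2,
            )
            n = 1
        return n

    def criteria(self) -> PICOSCriteria:
        """PICOS criteria whose element texts are the planted lexicons."""
        return validate_criteria(
            population=" ".join(self.lexicons.get("population", [])),
            intervention=" ".join(self.lexicons.get("intervention", [])),
            comparison=" ".join(self.lexicons.get("comparison", [])),
            outcome=" ".join(self.lexicons.get("outcome", [])),
            study_design=" ".join(self.lexicons.get("study_design", [])),
        )


@dataclass
class SyntheticCorpus:
    """Generated files, their parsed corpora and the gold label table."""

    spec: SyntheticCorpusSpec
    files: dict[str, str]  # filename -> file text (.ris / .nbib)
    corpora: dict[str, Corpus]  # database -> parsed corpus
    gold: pd.DataFrame  # columns: record_id, label (include/exclude)

    def merged(self) -> Corpus:
        return merge_corpora(*(self.corpora[db] for db in self.spec.databases))

    def gold_map(self) -> dict[str, str]:
        return dict(zip(self.gold["record_id"], self.gold["label"]))

    def write(self, outdir: str | Path) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for name, text in self.files.items():
            p = outdir / name
            p.write_text(text, encoding="utf-8")
            written.append(p)
        gold_path = outdir / "gold.csv"
        self.gold.to_csv(gold_path, index=False)
        written.append(gold_path)
        return written


@dataclass
class _Draft:
    title: str
    abstract: str
    authors: list[str]
    year: int
    journal: str
    doi: str | None
    database: str
    included: bool


def _pick(rng: np.random.Generator, pool: list[str], k: int) -> list[str]:
    idx = rng.choice(len(pool), size=min(k, len(pool)), replace=False)
    return [pool[i] for i in sorted(idx)]


def _make_draft(rng: np.random.Generator, spec: SyntheticCorpusSpec,
                i: int, included: bool, database: str) -> _Draft:
    pop = spec.lexicons.get("population", []) or ["population"]
    inter = spec.lexicons.get("intervention", []) or ["intervention"]
    out = spec.lexicons.get("outcome", []) or []
    if included:
        title_words = (
            _pick(rng, pop, 2) + _pick(rng, inter, 2) + _pick(rng, _FILLER_WORDS, 2)
        )
        abstract_words = (
            _pick(rng, pop, 2) + _pick(rng, inter, 2)
            + (_pick(rng, out, 1) if out else [])
            + _pick(rng, _FILLER_WORDS, 6)
        )
    else:
        title_words = _pick(rng, _DECOY_WORDS, 4) + _pick(rng, _FILLER_WORDS, 2)
        abstract_words = _pick(rng, _DECOY_WORDS, 5) + _pick(rng, _FILLER_WORDS, 6)
    order_t = rng.permutation(len(title_words))
    order_a = rng.permutation(len(abstract_words))
    title = " ".join(title_words[j] for j in order_t).capitalize()
    abstract = (
        " ".join(abstract_words[j] for j in order_a).capitalize()
        + f" results for study {i:05d}."
    )
    n_auth = int(rng.integers(1, 4))
    surnames = _pick(rng, _SURNAMES, n_auth)
    authors = [f"{s}, {chr(65 + int(rng.integers(0, 26)))}" for s in surnames]
    year = int(rng.integers(2015, 2026))
    doi = f"10.5555/synth.{i:05d}" if rng.random() < 0.7 else None
    return _Draft(
        title=title, abstract=abstract, authors=authors, year=year,
        journal=_JOURNALS[int(rng.integers(0, len(_JOURNALS)))],
        doi=doi, database=database, included=included,
    )


def _perturb_title(rng: np.random.Generator, title: str) -> str:
    """Superficial formatting noise: case, punctuation and whitespace only.

    The default dedup policy normalizes all three away, so a perturbed copy
    always matches its original's title key.
    """
    words = title.split()
    styled = []
    for w in words:
        r = rng.random()
        if r < 0.3:
            styled.append(w.upper())
        elif r < 0.5:
            styled.append(w.capitalize())
        else:
            styled.append(w.lower())
    sep = [" ", "  ", " - ", ", "]
    text = ""
    for j, w in enumerate(styled):
        text += w
        if j < len(styled) - 1:
            text += sep[int(rng.integers(0, len(sep)))]
    if rng.random() < 0.5:
        text += "."
    return text


def _ris_text(drafts: list[_Draft]) -> str:
    lines: list[str] = []
    for d in drafts:
        lines.append("TY  - JOUR")
        lines.append(f"TI  - {d.title}")
        for a in d.authors:
            lines.append(f"AU  - {a}")
        lines.append(f"PY  - {d.year}")
        lines.append(f"JO  - {d.journal}")
        if d.abstract:
            lines.append(f"AB  - {d.abstract}")
        if d.doi:
            lines.append(f"DO  - {d.doi}")
        lines.append("ER  - ")
    return "\n".join(lines) + "\n"


def _nbib_text(drafts: list[_Draft], pmid_offset: int) -> str:
    lines: list[str] = []
    for k, d in enumerate(drafts):
        lines.append(f"PMID- {pmid_offset + k}")
        lines.append(f"TI  - {d.title}")
        if d.abstract:
            lines.append(f"AB  - {d.abstract}")
        for a in d.authors:
            lines.append(f"FAU - {a}")
        lines.append(f"DP  - {d.year} Jan")
        lines.append(f"JT  - {d.journal}")
        if d.doi:
            lines.append(f"LID - {d.doi} [doi]")
        lines.append("")
    return "\n".join(lines) + "\n"


def generate_corpus(
    spec: SyntheticCorpusSpec, outdir: str | Path | None = None
) -> SyntheticCorpus:
    """Generate per-database citation files with gold labels.

    One ``.nbib`` file is written for a database named ``pubmed`` and one
    ``.ris`` file per other database.  Exactly
    ``round(n_records × prevalence)`` unique records are gold-included
    (minimum one).  ``round(n_records × duplicate_rate)`` records get a
    planted duplicate copy in another database, with title noise the
    default dedup policy must see through; blank abstracts are applied to
    ``round(n_records × blank_abstract_rate)`` unique records (duplicate
    copies are drawn from the non-blank ones so the blank count is exact
    after deduplication).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_records
    n_inc = spec.n_included()
    included_mask = np.zeros(n, dtype=bool)
    included_mask[rng.choice(n, size=n_inc, replace=False)] = True

    db_assign = [spec.databases[int(rng.integers(0, len(spec.databases)))] for _ in range(n)]
    drafts = [
        _make_draft(rng, spec, i, bool(included_mask[i]), db_assign[i]) for i in range(n)
    ]

    n_blank = round(n * spec.blank_abstract_rate)
    blank_idx = set(rng.choice(n, size=n_blank, replace=False).tolist()) if n_blank else set()
    for i in blank_idx:
        drafts[i].abstract = ""

    n_dup = round(n * spec.duplicate_rate)
    dup_sources: list[int] = []
    if n_dup and len(spec.databases) > 1:
        candidates = [i for i in range(n) if i not in blank_idx]
        if n_dup > len(candidates):
            n_dup = len(candidates)
        picked = rng.choice(len(candidates), size=n_dup, replace=False)
        dup_sources = [candidates[j] for j in sorted(picked)]
    dup_drafts: list[tuple[int, _Draft]] = []
    for i in dup_sources:
        src = drafts[i]
        others = [db for db in spec.databases if db != src.database]
        target_db = others[int(rng.integers(0, len(others)))]
        # half the copies keep the DOI (exercising the DOI rule), half drop
        # it (exercising title+author+year matching)
        keep_doi = rng.random() < 0.5 and src.doi is not None
        dup_drafts.append(
            (
                i,
                _Draft(
                    title=_perturb_title(rng, src.title),
                    abstract=src.abstract,
                    authors=list(src.authors),
                    year=src.year,
                    journal=src.journal,
                    doi=(src.doi.upper() if keep_doi and src.doi else None),
                    database=target_db,
                    included=src.included,
                ),
            )
        )

    per_db: dict[str, list[tuple[int, _Draft]]] = {db: [] for db in spec.databases}
    for i, d in enumerate(drafts):
        per_db[d.database].append((i, d))
    for i, d in dup_drafts:
        per_db[d.database].append((i, d))

    files: dict[str, str] = {}
    corpora: dict[str, Corpus] = {}
    gold_rows: list[tuple[str, str]] = []
    for db in spec.databases:
        pairs = per_db[db]
        db_drafts = [d for _, d in pairs]
        if db == "pubmed":
            text = _nbib_text(db_drafts, pmid_offset=10_000_000)
            files[f"{db}.nbib"] = text
            corpus = parse_nbib(text, source_db=db)
        else:
            text = _ris_text(db_drafts)
            files[f"{db}.ris"] = text
            corpus = parse_ris(text, source_db=db)
        if len(corpus) != len(db_drafts):
            raise AssertionError(f"round-trip mismatch for database {db}")
        corpora[db] = corpus
        for (src_i, _), rec in zip(pairs, corpus.records):
            gold_rows.append(
                (rec.record_id, "include" if drafts[src_i].included else "exclude")
            )

    gold = pd.DataFrame(gold_rows, columns=["record_id", "label"])
    result = SyntheticCorpus(spec=spec, files=files, corpora=corpora, gold=gold)
    if outdir is not None:
        result.write(outdir)
    return result


@dataclass
class RoleErrorModel:
    """Per-role sensitivity/specificity for simulated screening decisions.

    A gold-included record is voted *include* with probability
    ``sensitivity``; a gold-excluded record is voted *exclude* with
    probability ``specificity``; draws are independent across records and
    roles, seeded for reproducibility.
    """

    roles: dict[str, tuple[float, float]]  # role -> (sensitivity, specificity)
    seed: int = 0

    def __post_init__(self) -> None:
        for role, (sens, spec_) in self.roles.items():
            if not (0.0 <= sens <= 1.0 and 0.0 <= spec_ <= 1.0):
                raise ValueError(
                    f"sensitivity/specificity for role {role!r} must lie in [0, 1]"
                )

    @classmethod
    def uniform(cls, sensitivity: float, specificity: float, seed: int = 0,
                roles: tuple[str, ...] = ("reviewer", "critic", "arbitrator")) -> "RoleErrorModel":
        return cls(roles={r: (sensitivity, specificity) for r in roles}, seed=seed)


def simulate_role_decisions(
    gold: pd.DataFrame | Mapping[str, str], model: RoleErrorModel
) -> dict[str, pd.DataFrame]:
    """Per-role verdict tables drawn under the error model.

    Returns role → DataFrame(record_id, verdict), rows in gold order.
    """
    if isinstance(gold, pd.DataFrame):
        ids = gold.iloc[:, 0].astype(str).tolist()
        labels = gold.iloc[:, 1].astype(str).tolist()
    else:
        ids = [str(k) for k in gold]
        labels = [str(gold[k]) for k in gold]
    included = np.array([lab == "include" for lab in labels])
    out: dict[str, pd.DataFrame] = {}
    for role_idx, (role, (sens, spec_)) in enumerate(sorted(model.roles.items())):
        rng = np.random.default_rng([model.seed, role_idx])
        u = rng.random(len(ids))
        vote_include = np.where(included, u < sens, u >= spec_)
        out[role] = pd.DataFrame(
            {
                "record_id": ids,
                "verdict": np.where(vote_include, "include", "exclude"),
            }
        )
    return out
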