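"""Parsing of RIS and NBIB (MEDLINE) citation exports into structured records.

Both formats are line-tagged plain text.  RIS lines look like ``TI  - value``
and records terminate with ``ER  -``; NBIB lines look like ``TI  - value``
with 4-character left-padded tags (``PMID- 123``) and continuation lines
indented with spaces.  Parsers keep every tag they see in ``raw_fields`` so
that writing records back out loses nothing.

Record identifiers are assigned deterministically: a source-database-qualified
DOI if present, else PMID, else the source database plus a zero-padded
ordinal.  Qualifying by source database keeps ids unique when corpora from
several databases are merged before deduplication — the same publication
exported from two databases is two records until :func:`triscreen.dedup.deduplicate`
collapses it.
"""

from __future__ import annotations

import csv
import io
import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, TextIO

__all__ = [
    "ReferenceRecord",
    "Corpus",
    "ParseWarning",
    "parse_ris",
    "parse_nbib",
    "read_reference_file",
    "filter_blank_abstracts",
    "merge_corpora",
    "write_records_table",
    "read_records_table",
]


class ParseWarning(UserWarning):
    """Recoverable problem while parsing a citation export (record still emitted)."""


@dataclass
class ReferenceRecord:
    """One parsed citation.

    ``raw_fields`` maps each original tag to the list of values seen for it,
    verbatim and in file order, so a record round-trips without loss.
    """

    record_id: str
    source_db: str
    title: str = ""
    abstract: str = ""
    authors: list[str] = field(default_factory=list)
    year: int | None = None
    journal: str | None = None
    doi: str | None = None
    entry_type: str = ""
    raw_fields: dict[str, list[str]] = field(default_factory=dict)

    def has_abstract(self) -> bool:
        return bool(self.abstract.strip())


@dataclass
class Corpus:
    """An ordered collection of records with unique ids."""

    records: list[ReferenceRecord] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.record_id in seen:
                raise ValueError(f"duplicate record_id in corpus: {rec.record_id!r}")
            seen.add(rec.record_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ReferenceRecord]:
        return iter(self.records)

    def __getitem__(self, record_id: str) -> ReferenceRecord:
        for rec in self.records:
            if rec.record_id == record_id:
                return rec
        raise KeyError(record_id)

    def ids(self) -> list[str]:
        return [rec.record_id for rec in self.records]


def merge_corpora(*corpora: Corpus) -> Corpus:
    """Concatenate corpora (e.g. one per database) preserving order.

    Raises on record_id collision: ids are source-qualified, so a collision
    means the same file was merged twice.
    """
    records: list[ReferenceRecord] = []
    provenance: list[str] = []
    for c in corpora:
        records.extend(c.records)
        provenance.extend(c.provenance)
    return Corpus(records=records, provenance=provenance)


_YEAR_RE = re.compile(r"(\d{4})")


def _first_year(values: Iterable[str]) -> int | None:
    for v in values:
        m = _YEAR_RE.search(v)
        if m:
            return int(m.group(1))
    return None


def _normalize_doi(raw: str) -> str:
    doi = raw.strip()
    for prefix in ("https://doi.org/", "http://doi.org/", "doi.org/", "doi:"):
        if doi.lower().startswith(prefix):
            doi = doi[len(prefix):]
    return doi.strip()


def _assign_id(
    source_db: str, doi: str | None, pmid: str | None, ordinal: int, used: set[str]
) -> str:
    candidates = []
    if doi:
        candidates.append(f"{source_db}:{doi}")
    if pmid:
        candidates.append(f"{source_db}:pmid{pmid}")
    candidates.append(f"{source_db}:{ordinal:05d}")
    for cand in candidates:
        if cand not in used:
            used.add(cand)
            return cand
    # All collided (same DOI twice in one file): fall back to a suffixed ordinal.
    n = 2
    while f"{candidates[-1]}.{n}" in used:
        n += 1
    final = f"{candidates[-1]}.{n}"
    used.add(final)
    return final


def _first(fields: Mapping[str, list[str]], *tags: str) -> str | None:
    for tag in tags:
        if fields.get(tag):
            return fields[tag][0]
    return None


# --------------------------------------------------------------------------
# RIS

# Accept both "TY  - " (standard, two spaces) and "TY - " (single space),
# since vendor exports vary.
_RIS_TAG_RE = re.compile(r"^([A-Z][A-Z0-9])\s{1,2}-\s?(.*)$")


def parse_ris(stream: TextIO | str, source_db: str) -> Corpus:
    """Parse an RIS-tagged text stream into a :class:`Corpus`.

    Lines that do not open a new tag continue the previous tag's value
    (joined with a single space).  A record missing its ``ER`` terminator at
    end of file is still emitted, with a :class:`ParseWarning`.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    records: list[ReferenceRecord] = []
    used_ids: set[str] = set()
    fields: dict[str, list[str]] = {}
    last_tag: str | None = None
    open_record = False

    def emit() -> None:
        nonlocal fields, last_tag, open_record
        if fields:
            records.append(_ris_record(fields, source_db, len(records) + 1, used_ids))
        fields = {}
        last_tag = None
        open_record = False

    for line in stream:
        line = line.rstrip("\n").rstrip("\r")
        m = _RIS_TAG_RE.match(line)
        if m:
            tag, value = m.group(1), m.group(2)
            if tag == "ER":
                emit()
                continue
            open_record = True
            fields.setdefault(tag, []).append(value)
            last_tag = tag
        elif line.strip() and last_tag is not None:
            # continuation of the previous tag's value
            fields[last_tag][-1] = f"{fields[last_tag][-1]} {line.strip()}"
    if open_record and fields:
        warnings.warn(
            f"RIS record without 'ER  -' terminator at end of {source_db} input; "
            "record emitted anyway",
            ParseWarning,
            stacklevel=2,
        )
        emit()
    return Corpus(records=records, provenance=[f"{source_db} (ris)"])


def _ris_record(
    fields: dict[str, list[str]], source_db: str, ordinal: int, used: set[str]
) -> ReferenceRecord:
    doi_raw = _first(fields, "DO", "DI")
    doi = _normalize_doi(doi_raw) if doi_raw else None
    authors = list(fields.get("AU", [])) or list(fields.get("A1", []))
    year = _first_year(fields.get("PY", []) + fields.get("Y1", []))
    return ReferenceRecord(
        record_id=_assign_id(source_db, doi, None, ordinal, used),
        source_db=source_db,
        title=_first(fields, "TI", "T1") or "",
        abstract=_first(fields, "AB", "N2") or "",
        authors=authors,
        year=year,
        journal=_first(fields, "JO", "JF", "T2"),
        doi=doi,
        entry_type=_first(fields, "TY") or "",
        raw_fields=fields,
    )


# --------------------------------------------------------------------------
# NBIB / MEDLINE

_NBIB_TAG_RE = re.compile(r"^([A-Z0-9]{1,4})\s*-\s?(.*)$")


def parse_nbib(stream: TextIO | str, source_db: str) -> Corpus:
    """Parse an NBIB (PubMed MEDLINE) text stream into a :class:`Corpus`.

    Continuation lines (indented with spaces) are joined to the previous
    value with a single space.  A new ``PMID-`` line starts a new record.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    records: list[ReferenceRecord] = []
    used_ids: set[str] = set()
    fields: dict[str, list[str]] = {}
    last_tag: str | None = None

    def emit() -> None:
        nonlocal fields, last_tag
        if fields:
            records.append(_nbib_record(fields, source_db, len(records) + 1, used_ids))
        fields = {}
        last_tag = None

    for line in stream:
        line = line.rstrip("\n").rstrip("\r")
        if not line.strip():
            emit()
            continue
        if line[0].isspace():
            if last_tag is not None:
                fields[last_tag][-1] = f"{fields[last_tag][-1]} {line.strip()}"
            continue
        m = _NBIB_TAG_RE.match(line)
        if m:
            tag, value = m.group(1), m.group(2)
            if tag == "PMID" and fields:
                emit()
            fields.setdefault(tag, []).append(value)
            last_tag = tag
        elif last_tag is not None:
            fields[last_tag][-1] = f"{fields[last_tag][-1]} {line.strip()}"
    emit()
    return Corpus(records=records, provenance=[f"{source_db} (nbib)"])


def _nbib_doi(fields: Mapping[str, list[str]]) -> str | None:
    for tag in ("LID", "AID"):
        for value in fields.get(tag, []):
            if "[doi]" in value:
                return _normalize_doi(value.replace("[doi]", ""))
    return None


def _nbib_record(
    fields: dict[str, list[str]], source_db: str, ordinal: int, used: set[str]
) -> ReferenceRecord:
    pmid = _first(fields, "PMID")
    doi = _nbib_doi(fields)
    authors = list(fields.get("FAU", [])) or list(fields.get("AU", []))
    return ReferenceRecord(
        record_id=_assign_id(source_db, doi, pmid.strip() if pmid else None, ordinal, used),
        source_db=source_db,
        title=_first(fields, "TI") or "",
        abstract=_first(fields, "AB") or "",
        authors=authors,
        year=_first_year(fields.get("DP", [])),
        journal=_first(fields, "JT", "TA"),
        doi=doi,
        entry_type=_first(fields, "PT") or "",
        raw_fields=fields,
    )


def read_reference_file(
    path: str | Path, fmt: str, source_db: str, *, strict_decoding: bool = False
) -> Corpus:
    """Read a citation export from disk, tolerating a UTF-8 BOM.

    With ``strict_decoding`` undecodable bytes raise a :class:`ValueError`
    naming the byte offset; by default they are replaced with U+FFFD and a
    :class:`ParseWarning` is emitted so one bad byte does not discard a file.
    """
    raw = Path(path).read_bytes()
    try:
        text = raw.decode("utf-8-sig")
    except UnicodeDecodeError as exc:
        if strict_decoding:
            raise ValueError(
                f"undecodable byte at offset {exc.start} in {path}"
            ) from exc
        warnings.warn(
            f"undecodable byte at offset {exc.start} in {path}; replaced",
            ParseWarning,
            stacklevel=2,
        )
        text = raw.decode("utf-8-sig", errors="replace")
    if fmt == "ris":
        return parse_ris(text, source_db)
    if fmt == "nbib":
        return parse_nbib(text, source_db)
    raise ValueError(f"unknown format {fmt!r} (expected 'ris' or 'nbib')")


# --------------------------------------------------------------------------
# Filtering and tabular round-trip


def filter_blank_abstracts(corpus: Corpus) -> tuple[Corpus, Corpus]:
    """Partition a corpus into (kept, removed) by abstract presence.

    A record is removed when its abstract is empty or whitespace-only.
    Order is preserved in both halves.
    """
    kept = [r for r in corpus if r.has_abstract()]
    removed = [r for r in corpus if not r.has_abstract()]
    return (
        Corpus(records=kept, provenance=list(corpus.provenance)),
        Corpus(records=removed, provenance=list(corpus.provenance)),
    )


_TABLE_COLUMNS = [
    "record_id",
    "source_db",
    "title",
    "abstract",
    "authors",
    "year",
    "journal",
    "doi",
    "entry_type",
    "raw_fields",
]


def _record_to_row(rec: ReferenceRecord) -> dict[str, str]:
    return {
        "record_id": rec.record_id,
        "source_db": rec.source_db,
        "title": rec.title,
        "abstract": rec.abstract,
        "authors": json.dumps(rec.authors, ensure_ascii=False),
        "year": "" if rec.year is None else str(rec.year),
        "journal": "" if rec.journal is None else rec.journal,
        "doi": "" if rec.doi is None else rec.doi,
        "entry_type": rec.entry_type,
        "raw_fields": json.dumps(rec.raw_fields, ensure_ascii=False),
    }


def _row_to_record(row: Mapping[str, str]) -> ReferenceRecord:
    return ReferenceRecord(
        record_id=row["record_id"],
        source_db=row["source_db"],
        title=row["title"],
        abstract=row["abstract"],
        authors=json.loads(row["authors"]) if row["authors"] else [],
        year=int(row["year"]) if row["year"] else None,
        journal=row["journal"] or None,
        doi=row["doi"] or None,
        entry_type=row["entry_type"],
        raw_fields=json.loads(row["raw_fields"]) if row["raw_fields"] else {},
    )


def write_records_table(corpus: Corpus, path: str | Path, fmt: str = "csv") -> None:
    """Write a corpus to a CSV (RFC-4180 quoting) or JSON-lines table.

    List/mapping fields (authors, raw_fields) are JSON-encoded inside the CSV
    cells; embedded delimiters and newlines survive via quoting.  The written
    table reads back field-for-field identical with :func:`read_records_table`.
    """
    path = Path(path)
    if fmt == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=_TABLE_COLUMNS, quoting=csv.QUOTE_MINIMAL)
            writer.writeheader()
            for rec in corpus:
                writer.writerow(_record_to_row(rec))
    elif fmt == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for rec in corpus:
                fh.write(json.dumps(_record_to_row(rec), ensure_ascii=False) + "\n")
    else:
        raise ValueError(f"unknown table format {fmt!r} (expected 'csv' or 'jsonl')")


def read_records_table(path: str | Path, fmt: str | None = None) -> Corpus:
    """Read a corpus previously written by :func:`write_records_table`.

    Format is inferred from the extension when not given.  A malformed
    header raises with the list of missing columns.
    """
    path = Path(path)
    if fmt is None:
        fmt = "jsonl" if path.suffix in {".jsonl", ".ndjson"} else "csv"
    rows: list[Mapping[str, str]] = []
    if fmt == "csv":
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            header = reader.fieldnames or []
            missing = [c for c in _TABLE_COLUMNS if c not in header]
            if missing:
                raise ValueError(f"records table missing columns: {missing}")
            rows = list(reader)
    elif fmt == "jsonl":
        with path.open(encoding="utf-8") as fh:
            for line in fh:
                if not line.strip():
                    continue
                row = json.loads(line)
                missing = [c for c in _TABLE_COLUMNS if c not in row]
                if missing:
                    raise ValueError(f"records table missing columns: {missing}")
                rows.append(row)
    else:
        raise ValueError(f"unknown table format {fmt!r}")
    return Corpus(records=[_row_to_record(r) for r in rows], provenance=[str(path)])
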