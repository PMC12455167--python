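"""Cross-database deduplication of citation records.

The same publication retrieved from several databases must be collapsed to a
single record before screening.  Two records are considered duplicates when

* both carry DOIs and the normalized DOIs match, or
* their normalized titles match exactly and the companion fields
  (first-author surname, year) co-match, or
* fuzzy matching is enabled, the token-set title similarity reaches the
  threshold, and the companion fields co-match.

The duplicate relation is closed transitively into groups (a~b and b~c puts
all three in one group), matching reference-manager behaviour.  Each group
keeps one representative: the first member with a non-empty abstract, else
the earliest in input order.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from difflib import SequenceMatcher
from typing import Iterable

from triscreen.records import Corpus, ReferenceRecord

__all__ = ["DedupPolicy", "DedupReport", "DuplicateGroup", "normalize_title", "deduplicate"]


@dataclass(frozen=True)
class DedupPolicy:
    """Which signals establish that two records are the same publication.

    fuzzy_threshold, when set, must lie in (0.5, 1.0]; values at or below
    0.5 would merge unrelated titles.
    """

    use_doi: bool = True
    match_first_author: bool = True
    match_year: bool = True
    fuzzy_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.fuzzy_threshold is not None and not (0.5 < self.fuzzy_threshold <= 1.0):
            raise ValueError(
                f"fuzzy_threshold must be in (0.5, 1.0], got {self.fuzzy_threshold}"
            )


@dataclass
class DuplicateGroup:
    representative: str
    members: list[str]  # non-representative member ids

    @property
    def size(self) -> int:
        return 1 + len(self.members)


@dataclass
class DedupReport:
    groups: list[DuplicateGroup]
    n_in: int
    n_out: int

    def duplicate_groups(self) -> list[DuplicateGroup]:
        """Only the groups that actually collapsed records (size >= 2)."""
        return [g for g in self.groups if g.members]


def normalize_title(title: str) -> str:
    """Reduce a title to a comparison key.

    Casefolds, replaces every Unicode punctuation/dash/symbol-dash character
    with a space, collapses runs of whitespace to single spaces and strips
    the ends.
    """
    chars = []
    for ch in title.casefold():
        cat = unicodedata.category(ch)
        if cat.startswith("P") or cat in {"Sm", "Sk"} and ch in {"~", "^"}:
            chars.append(" ")
        else:
            chars.append(ch)
    return " ".join("".join(chars).split())


def _first_author_surname(rec: ReferenceRecord) -> str:
    if not rec.authors:
        return ""
    name = rec.authors[0]
    if "," in name:
        return name.split(",", 1)[0].strip().casefold()
    parts = name.split()
    return parts[-1].casefold() if parts else ""


def _normalize_doi_key(doi: str) -> str:
    return doi.strip().casefold()


def _token_set_similarity(a: str, b: str) -> float:
    """Order-insensitive title similarity on sorted unique tokens."""
    ta = " ".join(sorted(set(a.split())))
    tb = " ".join(sorted(set(b.split())))
    if not ta and not tb:
        return 1.0
    return SequenceMatcher(None, ta, tb).ratio()


class _UnionFind:
    def __init__(self, ids: Iterable[str]):
        self.parent = {i: i for i in ids}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _companions_match(a: ReferenceRecord, b: ReferenceRecord, policy: DedupPolicy) -> bool:
    if policy.match_first_author and _first_author_surname(a) != _first_author_surname(b):
        return False
    if policy.match_year and a.year != b.year:
        return False
    return True


def deduplicate(
    corpus: Corpus, policy: DedupPolicy | None = None
) -> tuple[Corpus, DedupReport]:
    """Collapse duplicate records, returning the unique corpus and a report.

    The unique corpus preserves the input order of the chosen
    representatives.  Every input id appears exactly once in the report,
    either as a representative or as a group member.
    """
    policy = policy or DedupPolicy()
    records = list(corpus.records)
    uf = _UnionFind(r.record_id for r in records)

    if policy.use_doi:
        by_doi: dict[str, str] = {}
        for rec in records:
            if rec.doi:
                key = _normalize_doi_key(rec.doi)
                if key in by_doi:
                    uf.union(by_doi[key], rec.record_id)
                else:
                    by_doi[key] = rec.record_id

    # Exact normalized-title matches, gated on companion fields.  Blocking by
    # title key keeps this linear in corpus size.
    by_title: dict[str, list[ReferenceRecord]] = {}
    for rec in records:
        key = normalize_title(rec.title)
        if key:
            by_title.setdefault(key, []).append(rec)
    for block in by_title.values():
        for i, a in enumerate(block):
            for b in block[i + 1:]:
                if _companions_match(a, b, policy):
                    uf.union(a.record_id, b.record_id)

    if policy.fuzzy_threshold is not None:
        # Block on companion fields; compare titles pairwise within blocks.
        by_companion: dict[tuple[str, int | None], list[ReferenceRecord]] = {}
        for rec in records:
            key = (_first_author_surname(rec), rec.year)
            by_companion.setdefault(key, []).append(rec)
        for block in by_companion.values():
            for i, a in enumerate(block):
                na = normalize_title(a.title)
                for b in block[i + 1:]:
                    if uf.find(a.record_id) == uf.find(b.record_id):
                        continue
                    if not _companions_match(a, b, policy):
                        continue
                    nb = normalize_title(b.title)
                    if _token_set_similarity(na, nb) >= policy.fuzzy_threshold:
                        uf.union(a.record_id, b.record_id)

    order = {r.record_id: i for i, r in enumerate(records)}
    by_id = {r.record_id: r for r in records}
    groups_by_root: dict[str, list[str]] = {}
    for rec in records:
        groups_by_root.setdefault(uf.find(rec.record_id), []).append(rec.record_id)

    groups: list[DuplicateGroup] = []
    rep_ids: set[str] = set()
    for member_ids in groups_by_root.values():
        member_ids.sort(key=order.__getitem__)
        with_abstract = [i for i in member_ids if by_id[i].has_abstract()]
        rep = with_abstract[0] if with_abstract else member_ids[0]
        groups.append(
            DuplicateGroup(representative=rep, members=[i for i in member_ids if i != rep])
        )
        rep_ids.add(rep)
    groups.sort(key=lambda g: order[g.representative])

    unique = Corpus(
        records=[r for r in records if r.record_id in rep_ids],
        provenance=list(corpus.provenance),
    )
    report = DedupReport(groups=groups, n_in=len(records), n_out=len(unique))
    return unique, report
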