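"""Corpus assembly: bibliographic records, selection criteria, tallies.

The analysis corpus is a deduplicated set of records that each carry a title
and at least one MeSH annotation.  Everything removed on the way in is
accounted for in an exclusion log, so ``|input| = |kept| + |excluded|``
always holds exactly.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

from .gazetteer import default_gazetteer
from .mesh_model import MeshEntity

__all__ = [
    "BibRecord",
    "Corpus",
    "ExclusionEntry",
    "apply_selection_criteria",
    "tally_by_year",
    "tally_by_country",
    "write_tally_csv",
    "write_exclusion_csv",
    "UNKNOWN_YEAR",
    "UNKNOWN_COUNTRY",
]

UNKNOWN_YEAR = "unknown"
UNKNOWN_COUNTRY = "UNK"

#: Fixed precedence of exclusion reasons; a record failing several checks is
#: logged once, under the first matching reason.
REASON_DUPLICATE = "duplicate"
REASON_NO_MESH = "no-mesh"
REASON_NO_TITLE = "no-title"
REASON_BLOCKLIST = "blocklist"


@dataclass
class BibRecord:
    """One bibliographic record (one PubMed article)."""

    pmid: int
    title: str | None = None
    entities: list[MeshEntity] = field(default_factory=list)
    year: int | None = None
    affiliations: list[str] = field(default_factory=list)
    language: str | None = None
    extras: dict[str, list[str]] = field(default_factory=dict)


class ExclusionEntry(NamedTuple):
    pmid: int
    reason: str
    detail: str


@dataclass
class Corpus:
    """Filtered record collection plus the log of everything excluded."""

    records: list[BibRecord]
    exclusions: list[ExclusionEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def pmids(self) -> list[int]:
        return [r.pmid for r in self.records]


def apply_selection_criteria(
    records: Iterable[BibRecord],
    blocklist: Iterable[int] | None = None,
) -> Corpus:
    """Deduplicate and filter *records* into a :class:`Corpus`.

    Kept records have a unique PMID (first occurrence wins), at least one
    MeSH entity and a title.  *blocklist* is an optional set of PMIDs judged
    irrelevant by manual curation; matching records are excluded last, with
    reason ``blocklist``.
    """
    blocked = set(blocklist or ())
    kept: list[BibRecord] = []
    log: list[ExclusionEntry] = []
    seen: set[int] = set()
    for rec in records:
        if rec.pmid in seen:
            log.append(ExclusionEntry(rec.pmid, REASON_DUPLICATE, "pmid already seen"))
            continue
        seen.add(rec.pmid)
        if not rec.entities:
            log.append(ExclusionEntry(rec.pmid, REASON_NO_MESH, "no MeSH annotations"))
        elif rec.title is None or not rec.title.strip():
            log.append(ExclusionEntry(rec.pmid, REASON_NO_TITLE, "missing title"))
        elif rec.pmid in blocked:
            log.append(ExclusionEntry(rec.pmid, REASON_BLOCKLIST, "manually excluded"))
        else:
            kept.append(rec)
    return Corpus(records=kept, exclusions=log)


def tally_by_year(corpus: Corpus) -> dict[int | str, int]:
    """Publication counts per year; records without a year go to "unknown"."""
    counts: Counter = Counter()
    for rec in corpus.records:
        counts[rec.year if rec.year is not None else UNKNOWN_YEAR] += 1
    return dict(counts)


def _normalize(segment: str) -> str:
    return segment.strip().strip(".;").strip().lower()


def tally_by_country(
    corpus: Corpus,
    gazetteer: Mapping[str, str] | None = None,
) -> dict[str, int]:
    """Publication counts per ISO-3 country code (first author's country).

    Each record contributes one count: its first affiliation string is split
    on commas and scanned right to left (country names conventionally close
    the affiliation); the first segment matching a gazetteer variant decides.
    Records with no affiliation or no match are counted under ``UNK``.
    """
    gaz = gazetteer if gazetteer is not None else default_gazetteer()
    if not gaz:
        raise ValueError("gazetteer must not be empty")
    norm_gaz = {_normalize(k): v for k, v in gaz.items()}
    counts: Counter = Counter()
    for rec in corpus.records:
        code = UNKNOWN_COUNTRY
        if rec.affiliations:
            for segment in reversed(rec.affiliations[0].split(",")):
                hit = norm_gaz.get(_normalize(segment))
                if hit is not None:
                    code = hit
                    break
        counts[code] += 1
    return dict(counts)


def write_tally_csv(tally: Mapping, path: str | Path, key_name: str = "key") -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow([key_name, "count"])
        for key in sorted(tally, key=str):
            writer.writerow([key, tally[key]])


def write_exclusion_csv(corpus: Corpus, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["pmid", "reason", "detail"])
        for entry in corpus.exclusions:
            writer.writerow(list(entry))
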