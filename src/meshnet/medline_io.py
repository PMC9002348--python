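"""Reader/writer for plain-text MEDLINE records (PubMed "PubMed format").

The format is line-oriented: a field starts with a tag of up to four
uppercase alphanumeric characters, space-padded to width four, followed by
``"- "`` and the value; long values continue on lines indented by six
spaces and are joined with a single space.  Records are separated by blank
lines.

Parsing is lossless and order-preserving: every non-blank input line is
attributed to exactly one field value or reported in the parse-issue list.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import IO, Iterable, NamedTuple

from .corpus import BibRecord
from .mesh_model import MeshEntity, label, parse_mesh_field

__all__ = [
    "RawRecord",
    "ParseIssue",
    "ParseResult",
    "parse_medline",
    "write_medline",
    "to_bib_record",
    "from_bib_record",
]

_TAG_RE = re.compile(r"^([A-Z0-9]{1,4}) {0,3}- (.*)$")
_CONTINUATION_INDENT = "      "  # six spaces, PubMed convention
_YEAR_RE = re.compile(r"\b(\d{4})\b")

#: Tags with dedicated BibRecord fields; everything else passes through.
_KNOWN_TAGS = {"PMID", "TI", "MH", "DP", "AD", "LA"}


@dataclass
class RawRecord:
    """One record as an ordered multimap of (tag, value) pairs."""

    fields: list[tuple[str, str]] = field(default_factory=list)

    def get(self, tag: str) -> list[str]:
        return [v for t, v in self.fields if t == tag]

    def first(self, tag: str) -> str | None:
        for t, v in self.fields:
            if t == tag:
                return v
        return None


class ParseIssue(NamedTuple):
    line_no: int  # 1-based line number in the input
    message: str
    text: str


class ParseResult(NamedTuple):
    records: list[RawRecord]
    issues: list[ParseIssue]


def parse_medline(source: str | IO[str] | Iterable[str]) -> ParseResult:
    """Parse MEDLINE text into records plus a list of parse issues.

    *source* may be a string, a text file object or an iterable of lines.
    Blocks without a PMID tag and unattributable lines are reported as
    issues, never silently dropped.
    """
    if isinstance(source, str):
        lines = source.splitlines()
    else:
        lines = [ln.rstrip("\n").rstrip("\r") for ln in source]

    records: list[RawRecord] = []
    issues: list[ParseIssue] = []

    block_fields: list[tuple[str, str]] = []
    block_start = 0

    def close_block(end_line: int) -> None:
        nonlocal block_fields
        if not block_fields:
            return
        rec = RawRecord(fields=block_fields)
        if rec.first("PMID") is None:
            issues.append(
                ParseIssue(block_start, "record block without PMID tag", block_fields[0][0])
            )
        else:
            records.append(rec)
        block_fields = []

    for idx, line in enumerate(lines, start=1):
        if not line.strip():
            close_block(idx)
            continue
        m = _TAG_RE.match(line)
        if m:
            if not block_fields:
                block_start = idx
            block_fields.append((m.group(1), m.group(2)))
        elif line.startswith("     "):  # ≥5 spaces marks a continuation
            if block_fields:
                tag, value = block_fields[-1]
                block_fields[-1] = (tag, value + " " + line.strip())
            else:
                issues.append(ParseIssue(idx, "continuation line outside any field", line))
        else:
            issues.append(ParseIssue(idx, "unparseable line (no tag, not indented)", line))
    close_block(len(lines) + 1)
    return ParseResult(records, issues)


def _wrap_value(head: str, value: str, width: int) -> list[str]:
    """Wrap ``head + value`` to *width* columns, breaking only at single
    spaces so re-parsing (join with one space) reproduces *value* exactly."""
    out: list[str] = []
    prefix = head
    remainder = value
    while len(prefix) + len(remainder) > width:
        avail = width - len(prefix)
        brk = -1
        for i, ch in enumerate(remainder):
            if (
                ch == " "
                and 0 < i
                and remainder[i - 1] != " "
                and (i + 1 == len(remainder) or remainder[i + 1] != " ")
            ):
                if i <= avail:
                    brk = i
                elif brk == -1:
                    brk = i  # no break fits: take the earliest legal one
                    break
                else:
                    break
        if brk <= 0:
            break  # unbreakable; emit over-width line
        out.append(prefix + remainder[:brk])
        remainder = remainder[brk + 1 :]
        prefix = _CONTINUATION_INDENT
    out.append(prefix + remainder)
    return out


def write_medline(records: Iterable[RawRecord], width: int = 80) -> str:
    """Serialise *records* to MEDLINE text; inverse of :func:`parse_medline`."""
    blocks: list[str] = []
    for rec in records:
        lines: list[str] = []
        for tag, value in rec.fields:
            if "\n" in value or "\r" in value:
                raise ValueError(f"field {tag} value contains a newline: {value!r}")
            head = tag.ljust(4) + "- "
            lines.extend(_wrap_value(head, value, width))
        blocks.append("\n".join(lines))
    if not blocks:
        return ""
    return "\n\n".join(blocks) + "\n"


def to_bib_record(raw: RawRecord) -> BibRecord:
    """Map a :class:`RawRecord` onto the typed :class:`BibRecord`.

    PMID must be numeric; an unparseable DP simply leaves the year absent.
    Tags without a dedicated field are preserved in ``extras``.
    """
    pmid_text = raw.first("PMID")
    if pmid_text is None:
        raise ValueError("record has no PMID field")
    try:
        pmid = int(pmid_text)
    except ValueError:
        raise ValueError(f"non-numeric PMID: {pmid_text!r}") from None

    year: int | None = None
    dp = raw.first("DP")
    if dp:
        m = _YEAR_RE.search(dp)
        if m:
            year = int(m.group(1))

    extras: dict[str, list[str]] = {}
    for tag, value in raw.fields:
        if tag not in _KNOWN_TAGS:
            extras.setdefault(tag, []).append(value)

    return BibRecord(
        pmid=pmid,
        title=raw.first("TI"),
        entities=[parse_mesh_field(v) for v in raw.get("MH")],
        year=year,
        affiliations=raw.get("AD"),
        language=raw.first("LA"),
        extras=extras,
    )


def from_bib_record(rec: BibRecord) -> RawRecord:
    """Inverse of :func:`to_bib_record` (up to field ordering)."""
    fields: list[tuple[str, str]] = [("PMID", str(rec.pmid))]
    if rec.title is not None:
        fields.append(("TI", rec.title))
    for ent in rec.entities:
        fields.append(("MH", label(ent, "distinct")))
    if rec.year is not None:
        fields.append(("DP", str(rec.year)))
    for aff in rec.affiliations:
        fields.append(("AD", aff))
    if rec.language is not None:
        fields.append(("LA", rec.language))
    for tag, values in rec.extras.items():
        for v in values:
            fields.append((tag, v))
    return RawRecord(fields=fields)
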