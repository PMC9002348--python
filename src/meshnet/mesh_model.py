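"""MeSH annotation model.

A MEDLINE ``MH`` field value is a descriptor, optionally refined by a
qualifier (subheading) after a ``/``, with an asterisk marking the term as a
*major topic* of the article.  In this pipeline the asterisked and plain
forms of a heading are distinct analytic units ("concepts"), as are
descriptor/qualifier combinations: ``Health Equity``, ``*Health Equity`` and
``Health Equity/*organization & administration`` are three different nodes
in the semantic network.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["MeshEntity", "MeshFieldError", "parse_mesh_field", "label", "LABEL_MODES"]

LABEL_MODES = ("distinct", "merged")


class MeshFieldError(ValueError):
    """Raised for an MH field value that cannot be interpreted."""


@dataclass(frozen=True)
class MeshEntity:
    """One MeSH concept: descriptor, optional qualifier, major-topic flag.

    ``major_on_qualifier`` records where the asterisk sat in the source text
    (``*D/Q`` vs ``D/*Q``) so labels round-trip exactly; analytically the
    flag is a single per-entity boolean.
    """

    descriptor: str
    qualifier: str | None = None
    major: bool = False
    major_on_qualifier: bool = field(default=False, compare=True)

    def __post_init__(self) -> None:
        if not self.descriptor or self.descriptor != self.descriptor.strip():
            raise MeshFieldError(f"bad descriptor: {self.descriptor!r}")
        if "/" in self.descriptor or self.descriptor.startswith("*"):
            raise MeshFieldError(f"bad descriptor: {self.descriptor!r}")
        if self.qualifier is not None:
            if not self.qualifier or "/" in self.qualifier or self.qualifier.startswith("*"):
                raise MeshFieldError(f"bad qualifier: {self.qualifier!r}")
        if self.major_on_qualifier and (self.qualifier is None or not self.major):
            raise MeshFieldError("major_on_qualifier requires a qualifier and major=True")

    def label(self, mode: str = "distinct") -> str:
        return label(self, mode)


def parse_mesh_field(raw: str) -> MeshEntity:
    """Parse one MH field value into a :class:`MeshEntity`.

    ``"D"`` → plain; ``"*D"`` → major; ``"D/Q"`` → qualified; ``"D/*Q"`` →
    qualified major (asterisk at the qualifier position).  Internal casing
    and spacing of the heading text are preserved verbatim.
    """
    text = raw.strip()
    if not text or text == "*":
        raise MeshFieldError(f"empty MH value: {raw!r}")
    if text.count("/") > 1:
        raise MeshFieldError(f"more than one '/' in MH value: {raw!r}")

    if "/" in text:
        desc_part, qual_part = (p.strip() for p in text.split("/"))
    else:
        desc_part, qual_part = text, None

    major_desc = desc_part.startswith("*")
    if major_desc:
        desc_part = desc_part[1:].strip()
    major_qual = qual_part is not None and qual_part.startswith("*")
    if major_qual:
        qual_part = qual_part[1:].strip()
    if major_desc and major_qual:
        raise MeshFieldError(f"asterisk on both descriptor and qualifier: {raw!r}")
    if not desc_part or (qual_part is not None and not qual_part):
        raise MeshFieldError(f"empty descriptor or qualifier: {raw!r}")

    return MeshEntity(
        descriptor=desc_part,
        qualifier=qual_part,
        major=major_desc or major_qual,
        major_on_qualifier=major_qual,
    )


def label(entity: MeshEntity, mode: str = "distinct") -> str:
    """Render the node label for *entity*.

    ``distinct`` (default) keeps major-topic and qualifier variants as
    separate labels, with the asterisk at its original position.  ``merged``
    collapses every variant onto the bare descriptor.
    """
    if mode == "merged":
        return entity.descriptor
    if mode != "distinct":
        raise ValueError(f"unknown label mode: {mode!r} (expected one of {LABEL_MODES})")
    if entity.qualifier is None:
        return ("*" if entity.major else "") + entity.descriptor
    if entity.major and entity.major_on_qualifier:
        return f"{entity.descriptor}/*{entity.qualifier}"
    star = "*" if entity.major else ""
    return f"{star}{entity.descriptor}/{entity.qualifier}"
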