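"""Synthetic MEDLINE corpus generator.

Emulates the statistical shape of a PubMed health-equity corpus so the whole
pipeline is testable without live database queries:

* a near-universal check tag ("Humans") present on almost every record;
* descriptor popularity following a Zipf law, giving the heavy-tailed degree
  hierarchy (universal tag ≫ demographic tags ≫ topical tags) seen in real
  MeSH indexing;
* 1–30 annotations per record (≥1-truncated Poisson), each with optional
  qualifier and major-topic flag;
* publication years uniform over a range and one affiliation string ending
  in a country name drawn from skewed per-country weights.

Everything is driven by a single integer seed: identical parameters and seed
yield byte-identical MEDLINE output (numpy PCG64 generator).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .corpus import BibRecord, Corpus
from .gazetteer import COUNTRY_NAMES
from .medline_io import from_bib_record, write_medline
from .mesh_model import MeshEntity

__all__ = [
    "GeneratorParams",
    "vocabulary",
    "zipf_weights",
    "generate_corpus",
    "generate_medline",
    "corrupt_records",
    "toy_fixture",
    "TOY4_LABELS",
]

#: Realistic heading stock placed at the head of the synthetic vocabulary, so
#: popular synthetic descriptors carry meaningful names (and ego-subnetwork
#: seeds such as "Health Equity" exist in generated corpora).
BASE_DESCRIPTORS: tuple[str, ...] = (
    "Health Equity",
    "Vulnerable Populations",
    "Social Determinants of Health",
    "Culture",
    "Trust",
    "Health Literacy",
    "Education",
    "Female",
    "Male",
    "United States",
    "Middle Aged",
    "Poverty",
    "Healthcare Disparities",
    "Socioeconomic Factors",
    "Adolescent",
    "Aged",
    "Adult",
    "Child",
    "Health Services Accessibility",
    "SARS-CoV-2",
    "COVID-19",
    "Health Promotion",
    "Attitude to Health",
    "Patient Acceptance of Health Care",
    "Health Policy",
    "Health Status Disparities",
    "Social Justice",
    "Racism",
    "Minority Groups",
    "Cultural Diversity",
    "Cultural Competency",
    "Language",
    "Qualitative Research",
    "Surveys and Questionnaires",
    "Educational Status",
    "Social Support",
    "Social Class",
    "Housing",
    "Income",
    "Communication",
)

DEFAULT_QUALIFIERS: tuple[str, ...] = (
    "organization & administration",
    "education",
    "ethnology",
    "psychology",
    "standards",
    "trends",
    "methods",
    "epidemiology",
    "economics",
    "ethics",
    "statistics & numerical data",
    "rehabilitation",
)

#: Per-country sampling weights, skewed toward the countries that dominate
#: the health-equity literature.
DEFAULT_COUNTRY_WEIGHTS: dict[str, float] = {
    "USA": 40.0,
    "CAN": 9.0,
    "AUS": 7.0,
    "GBR": 7.0,
    "BRA": 3.0,
    "CHE": 2.0,
    "DEU": 2.0,
    "SWE": 2.0,
    "FRA": 2.0,
    "NLD": 2.0,
    "ESP": 2.0,
    "IND": 2.0,
    "MEX": 2.0,
    "CHN": 2.0,
    "NOR": 1.5,
    "DNK": 1.5,
    "THA": 1.0,
    "COL": 1.0,
    "KEN": 1.0,
    "ETH": 1.0,
    "IRL": 1.0,
    "ITA": 1.0,
    "PER": 1.0,
    "ARG": 1.0,
}

UNIVERSAL_TAG = "Humans"
MAX_TERMS_PER_RECORD = 30
_PMID_BASE = 100001


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the corpus generator; defaults emulate the study corpus
    (circa 950 records, 2014–2021, Humans on essentially every record)."""

    vocab_size: int = 500
    zipf_exponent: float = 1.2
    universal_prob: float = 0.98
    terms_per_record: float = 12.0  # Poisson rate, truncated to >= 1
    major_prob: float = 0.30
    qualifier_prob: float = 0.15
    qualifier_vocab: tuple[str, ...] = DEFAULT_QUALIFIERS
    year_range: tuple[int, int] = (2014, 2021)
    country_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COUNTRY_WEIGHTS)
    )
    n_records: int = 950
    seed: int = 0

    def validate(self) -> None:
        for name in ("universal_prob", "major_prob", "qualifier_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.vocab_size < 1 or self.n_records < 1:
            raise ValueError("vocab_size and n_records must be positive")
        if self.zipf_exponent <= 0:
            raise ValueError("zipf_exponent must be > 0")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError(f"year_range out of order: {self.year_range}")
        if not self.country_weights or not any(w > 0 for w in self.country_weights.values()):
            raise ValueError("country_weights must contain a positive weight")
        if self.terms_per_record <= 0:
            raise ValueError("terms_per_record must be > 0")
        if self.terms_per_record > self.vocab_size + 1:
            raise ValueError(
                f"terms_per_record={self.terms_per_record} exceeds vocab_size+1={self.vocab_size + 1}"
            )


def vocabulary(vocab_size: int) -> list[str]:
    """The descriptor vocabulary: realistic headings first, then filler."""
    vocab = list(BASE_DESCRIPTORS[:vocab_size])
    vocab.extend(f"Topic {i:04d}" for i in range(len(vocab) + 1, vocab_size + 1))
    return vocab


def zipf_weights(n: int, exponent: float) -> np.ndarray:
    """Normalized Zipf popularity weights over ranks 1..n."""
    w = np.arange(1, n + 1, dtype=float) ** -exponent
    return w / w.sum()


def generate_corpus(params: GeneratorParams) -> list[BibRecord]:
    """Draw a fully deterministic synthetic record list from *params*."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    vocab = vocabulary(params.vocab_size)
    weights = zipf_weights(params.vocab_size, params.zipf_exponent)

    isos = sorted(params.country_weights)
    cw = np.array([params.country_weights[i] for i in isos], dtype=float)
    cw = cw / cw.sum()

    y0, y1 = params.year_range
    max_k = min(MAX_TERMS_PER_RECORD, params.vocab_size)
    records: list[BibRecord] = []
    for i in range(params.n_records):
        pmid = _PMID_BASE + i
        k = 0
        while k == 0:
            k = int(rng.poisson(params.terms_per_record))
        k = min(k, max_k)
        idx = rng.choice(params.vocab_size, size=k, replace=False, p=weights)

        entities: list[MeshEntity] = []
        if rng.random() < params.universal_prob:
            entities.append(MeshEntity(UNIVERSAL_TAG))
        for j in idx:
            major = bool(rng.random() < params.major_prob)
            qualifier = None
            if params.qualifier_vocab and rng.random() < params.qualifier_prob:
                qualifier = params.qualifier_vocab[rng.integers(len(params.qualifier_vocab))]
            entities.append(
                MeshEntity(
                    descriptor=vocab[j],
                    qualifier=qualifier,
                    major=major,
                    major_on_qualifier=major and qualifier is not None,
                )
            )

        iso = isos[int(rng.choice(len(isos), p=cw))]
        country = COUNTRY_NAMES.get(iso, iso)
        year = int(rng.integers(y0, y1 + 1))
        language = "eng" if rng.random() < 0.983 else "spa"
        records.append(
            BibRecord(
                pmid=pmid,
                title=f"Synthetic record {pmid} on {vocab[idx[0]]}",
                entities=entities,
                year=year,
                affiliations=[f"Department of Public Health, National University, {country}."],
                language=language,
            )
        )
    return records


def generate_medline(params: GeneratorParams) -> str:
    """Generated corpus serialised as MEDLINE plain text."""
    return write_medline(from_bib_record(r) for r in generate_corpus(params))


def corrupt_records(
    records: list[BibRecord],
    duplicate_rate: float = 0.0,
    no_title_rate: float = 0.0,
    no_mesh_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[BibRecord], dict[str, int]]:
    """Inject selection-criteria violations at exact counts.

    ``round(rate * n)`` records are hit per defect; the no-title and no-mesh
    target sets are disjoint so each violation maps to exactly one exclusion
    reason.  Duplicates are appended copies (originals stay first, so every
    copy is excluded as a duplicate).  Returns the corrupted list and the
    injected counts, which selection must reproduce exactly.
    """
    rng = np.random.default_rng(seed)
    n = len(records)
    n_dup = int(round(duplicate_rate * n))
    n_no_title = int(round(no_title_rate * n))
    n_no_mesh = int(round(no_mesh_rate * n))
    if n_no_title + n_no_mesh > n:
        raise ValueError("no_title_rate + no_mesh_rate exceed the record count")

    perm = rng.permutation(n)
    title_idx = set(perm[:n_no_title].tolist())
    mesh_idx = set(perm[n_no_title : n_no_title + n_no_mesh].tolist())

    out: list[BibRecord] = []
    for i, rec in enumerate(records):
        if i in title_idx:
            rec = replace(rec, title=None)
        elif i in mesh_idx:
            rec = replace(rec, entities=[])
        out.append(rec)
    dup_sources = rng.choice(n, size=n_dup, replace=False) if n_dup else []
    for i in dup_sources:
        out.append(replace(out[int(i)]))
    counts = {"duplicate": n_dup, "no-title": n_no_title, "no-mesh": n_no_mesh}
    return out, counts


#: Node labels of the four-article toy corpus, for readable tests.
TOY4_LABELS = {
    "H": "Humans",
    "E": "Health Equity",
    "V": "Vulnerable Populations",
    "C": "Culture",
    "T": "Trust",
}


def toy_fixture() -> Corpus:
    """Four hand-written records whose semantic network is known exactly.

    Annotation sets: A1={H,E,V}, A2={H,E,C}, A3={H,V}, A4={H,C,T}. The
    concept projection has 5 nodes and 7 edges with total weight 10.
    """
    H, E, V, C, T = (TOY4_LABELS[x] for x in "HEVCT")
    sets = [(1, [H, E, V]), (2, [H, E, C]), (3, [H, V]), (4, [H, C, T])]
    records = [
        BibRecord(
            pmid=pmid,
            title=f"T{pmid}",
            entities=[MeshEntity(d) for d in descriptors],
            year=2020,
            affiliations=["Instituto Nacional de Salud, Mexico City, Mexico."],
            language="eng",
        )
        for pmid, descriptors in sets
    ]
    return Corpus(records=records, exclusions=[])
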