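# Methods

## The semantic-network model

A bibliographic corpus is modelled as a bipartite incidence structure:
articles (identified by PMID) on one side, MeSH concepts on the other, with a
membership for every annotation.  The **concept projection** is the semantic
network proper: concepts a and b are linked iff at least one article carries
both, with integer weight w(a,b) equal to the number of such articles.  The
dual **article projection** links articles by the number of concepts they
share.  Both are simple undirected graphs — no self-loops, no parallel
edges — and both satisfy an exact conservation law used throughout the test
suite: the total edge weight of the concept projection equals
Σ over articles of C(t, 2), where t is the article's count of distinct
concept labels (dually for articles).  No edge-weight threshold is applied by
default; a minimum-weight filter is available in the CLI and library.

Concept identity follows the indexing convention that a major-topic
annotation (asterisked) and a descriptor/qualifier combination are *different
analytic units* from the bare descriptor.  The default `distinct` label mode
therefore keeps `Culture`, `*Culture` and `Culture/ethnology` as three nodes;
the optional `merged` mode collapses all variants onto the bare descriptor.
Labels are compared case-sensitively and verbatim: MeSH is a controlled
vocabulary with canonical casing, so normalisation would merge nothing real
and could mask data errors.  The entity model records on which side of the
`/` the asterisk sat (`*D/Q` vs `D/*Q`) purely so labels round-trip exactly;
analytically the major flag is a single boolean.  No validation against the
MeSH thesaurus is attempted — annotations are taken as given.

## Topology statistics

Degree k is the **unweighted** adjacent-node count; this is the quantity for
which a tag present on every article attains exactly |V| − 1, which is how
the near-universal *Humans* tag behaves in real corpora.  Strength (sum of
incident weights) is reported separately.  Rank R orders nodes by descending
degree with ties broken by ascending label; published rankings print distinct
ranks for equal-degree nodes without stating a rule, so the package documents
its tie-break as a convention chosen to be deterministic and independent of
node insertion order (a property the suite checks by permutation).

Betweenness and closeness use standard unweighted shortest-path definitions
(networkx); closeness uses the Wasserman–Faust improvement, which scales
per-component closeness by the component's size fraction on disconnected
graphs, and an isolated node has closeness 0.  Density is 2|E| / (|V|(|V|−1)).
The degree distribution is binned by exact integer degree — the networks are
small enough that binning would only lose information.  The core/periphery
partition is intentionally simple: the top q-fraction of nodes by degree
(degree ≥ the empirical (1−q) degree quantile, linear interpolation) is the
core.  It is a descriptive cut, not a statistical core–periphery fit.

## Subnetwork extraction

Thematic subnetworks are **induced** subgraphs on a seed set plus every node
within graph distance `radius` (default 1, the first neighbors): every parent
edge between retained nodes survives with its weight.  Induced extraction —
rather than keeping only seed-incident edges — is what makes thematic
subnetworks dense, matching how such figures are drawn in practice; a star of
seed-incident edges could never reach the observed edge counts.  Multi-seed
specs take the union of per-seed neighborhoods.  An unknown seed raises an
error naming the label and suggesting the nearest node labels
(difflib close matches).  A convenience flag additionally seeds the `*`-major
twin of each seed when present, since a theme usually spans both forms;
whether to use it is the analyst's choice and neither behaviour is claimed
as canonical.

## Corpus selection and tallies

Selection keeps the first occurrence of each PMID and requires at least one
MeSH annotation and a title.  Every removal is logged with exactly one
reason, in the fixed precedence duplicate → no-mesh → no-title, so
|input| = |kept| + |excluded| holds exactly and selection is idempotent on an
already-valid corpus.  Relevance screening is inherently manual; it is
supported as an optional PMID blocklist (reason `blocklist`, applied after
the automatic criteria), never as an automated judgment.

Year tallies use the first four-digit token of the DP field (all DP variants
— "2015", "2015 Mar-Apr" — begin with the year); records without one land in
an explicit `unknown` bucket.  Country tallies assign **one country per
record**: the first affiliation string is split on commas and scanned right
to left (affiliations conventionally end with the country), and the first
segment matching the gazetteer decides; no match counts as `UNK`.
Multi-country fractional counting is out of scope.  The gazetteer is a small
bundled mapping of country-name variants ("UK", "United Kingdom",
"England" → GBR) to ISO-3 codes, curated for the countries that actually
publish in this literature; callers may substitute their own mapping.

## MEDLINE I/O

The parser accepts the PubMed plain-text export dialect: a tag of up to four
uppercase alphanumerics padded to width four, `"- "`, the value;
continuation lines indented by at least five spaces, joined with a single
space; blank lines between records.  Parsing is lossless — every non-blank
line is attributed to exactly one field value or reported in a line-addressed
parse-issue list (blocks without a PMID, unattributable lines) — and
order-preserving.  The writer wraps at 80 columns, breaking values only at
single spaces so that `parse(write(x)) == x` exactly; an unbreakable token
is emitted over-width rather than corrupted, so the round trip is
width-invariant.  Input is assumed UTF-8 with undecodable bytes replaced.
XML PubMed format, RIS/BibTeX and live E-utilities querying are non-goals.

## The synthetic generator

The generator emulates the statistical structure this analysis relies on,
not any particular corpus's content:

| parameter | default | why |
|---|---|---|
| `n_records` | 950 | a realistic single-search corpus size |
| `year_range` | (2014, 2021) | the span of recent health-equity literature |
| `universal_prob` | 0.98 | the Humans check tag is on essentially every human-health record |
| `vocab_size` | 500 | distinct descriptors at this corpus scale |
| `zipf_exponent` | 1.2 | MeSH usage is heavy-tailed; a Zipf law reproduces the universal ≫ demographic ≫ topical degree hierarchy |
| `terms_per_record` | 12.0 | typical MEDLINE indexing depth; Poisson rate, truncated to ≥ 1 and capped at 30 |
| `major_prob` / `qualifier_prob` | 0.30 / 0.15 | a minority of annotations are major topics; qualifiers are rarer |
| `country_weights` | USA-heavy | publication output is concentrated in a few countries |

`terms_per_record` is the Poisson rate *before* ≥1 truncation; at rates ≥ 3
the truncated mean differs negligibly and the rate parameterisation is exact
to state.  The descriptor vocabulary puts a stock of realistic headings
first (so the popular synthetic concepts carry meaningful names and
ego-subnetwork seeds exist in generated corpora) and pads with numbered
filler topics.  All randomness flows from a single integer seed through
numpy's PCG64 generator: identical parameters and seed give byte-identical
MEDLINE output across runs and platforms.

A corruption helper injects selection violations at **exact counts**
(`round(rate·n)` per defect, disjoint no-title/no-mesh target sets,
duplicates appended after their originals), so filter tests compare the
exclusion log against known injections rather than sampled estimates.

What the generator does **not** emulate: correlated term co-selection
(real MeSH annotations cluster thematically; here descriptors are drawn
independently per record from one popularity law), entry-term synonymy, the
MeSH tree hierarchy, citation structure, abstracts, or multi-affiliation
author lists.  Passing tests therefore demonstrate the pipeline's structural
correctness (projection semantics, accounting, determinism, contracts), not
that any particular real corpus's numbers would be reproduced — those depend
on a dated snapshot of a live database.

## Problem sizes and numerical choices

The test suite exercises the projection oracle on 200 generated corpora of
up to 50 records over 40 descriptors, round-trips 100 corpora, and checks
rank and subgraph contracts on 100 random graphs each; the acceptance script
runs one full study-scale pipeline (950 records, ~1,900 concept nodes).
Floating-point outputs are printed with 6 significant digits; CSVs are
UTF-8, comma-delimited, with a header row.  The brute-force oracles used in
tests follow a deliberately different route (label→article inverted index
with pairwise set intersections) from the implementation's per-article pair
enumeration, and the MEDLINE parser is additionally cross-checked against
Bio.Medline on generated text.

## Known limitations

- Country attribution uses the first affiliation string only and exact
  (normalised) segment matching; affiliations whose trailing segment embeds
  an e-mail address fall to `UNK`.
- `merged` label mode collapses variants but does not merge entry-term
  synonyms or tree ancestors.
- Centralities are unweighted; weighted shortest-path variants, community
  detection, statistical edge backboning and per-year network slicing are
  out of scope.
- The rank tie-break is a documented convention; published rankings from
  other tools may order equal-degree nodes differently.
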