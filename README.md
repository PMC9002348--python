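# meshnet

Weighted MeSH co-occurrence semantic networks from MEDLINE corpora.

## What it is for

Bibliometric studies of a research field often start from a PubMed search,
export the hits as plain-text MEDLINE records, and ask: *which concepts
dominate the scholarly discussion, and how are they connected?*  Each MEDLINE
record carries curated **MeSH** (Medical Subject Headings) annotations — a
descriptor, optionally refined by a qualifier after a `/`, with an asterisk
marking a *major topic* (`*Vulnerable Populations`,
`Health Equity/*organization & administration`).  `meshnet` turns such a
corpus into a **semantic network**: nodes are MeSH concepts (asterisked and
qualified variants are distinct analytic units), and an edge joins two
concepts whenever some article is annotated with both, weighted by the number
of such articles.

Formally, from the bipartite article–concept incidence the package computes
both one-mode projections.  For the concept projection, the weight of edge
{a, b} is w(a,b) = |{articles annotated with both a and b}|, and the total
edge weight obeys the conservation law Σ_{a,b} w(a,b) = Σ_articles C(t, 2)
with t the number of distinct concepts on an article.  Per node the package
reports the unweighted degree *k* (adjacent-concept count), the rank *R*
(position by descending degree, ties broken by label so ranking is a
deterministic bijection onto 1..|V|), strength (sum of incident weights),
betweenness, closeness and clustering, plus global statistics (density,
components, degree distribution).  A near-universal check tag such as
*Humans* is the structural benchmark: present on every article, it attains
k = |V| − 1.

The toolkit also covers the surrounding pipeline: a lossless reader/writer
for plain-text MEDLINE, the corpus selection criteria (deduplication by
PMID, at-least-one-MeSH, has-title, optional manual blocklist) with an exact
exclusion log, publication tallies by year and by country (first author's
affiliation, via a bundled gazetteer), seed + first-neighbor induced
subnetworks for thematic analysis, and a seeded synthetic-corpus generator
(Zipf-skewed descriptor popularity, near-universal tag, qualifier and
major-topic sampling) so every stage is testable without live database
queries.

## Worked example

Simulate a small corpus and rank its concepts:

```sh
meshnet simulate --seed 5 --n-records 30 -o corpus.txt
meshnet stats corpus.txt --top 8 --outdir statsout
```

prints

```
   R      k  label
   1    184  Humans
   2    116  Social Determinants of Health
   3    103  Vulnerable Populations
   4     96  Health Equity
   5     65  *Health Equity
   6     65  Health Literacy
   7     64  Culture
   8     63  Trust
```

`Humans` tops the ranking — it is on essentially every record, so its degree
(184) approaches the node count minus one.  Note `*Health Equity` (major
topic) ranks separately from `Health Equity`: the two are distinct concepts.
Equal degrees (65, 65) still receive distinct ranks, broken by label.
`statsout/node_stats.csv` holds the full per-node table and
`statsout/global_stats.json` the global statistics.

The built-in four-article toy corpus (annotation sets {H,E,V}, {H,E,C},
{H,V}, {H,C,T}) runs through the whole pipeline with known answers:

```sh
meshnet run --toy --outdir toyout --seed-term "Health Equity"
```

The manifest reports 5 concept nodes and 7 edges (total weight 10 =
C(3,2)+C(3,2)+C(2,2)+C(3,2)), and the `Health Equity` first-neighbor
subnetwork has 4 nodes and 5 edges — the induced subgraph keeps the
Humans–Vulnerable Populations and Humans–Culture edges between neighbors,
not just the seed-incident ones.

The same operations are available as a library:

```python
from meshnet import toy_fixture, build_bipartite, project_concepts, compute_node_stats

net = project_concepts(build_bipartite(toy_fixture()))
report = compute_node_stats(net)
print(report.nodes[0])   # NodeStat(label='Humans', k=4, R=1, strength=7, ...)
```

## Layout

- `src/meshnet/medline_io.py` — plain-text MEDLINE parser/writer (lossless round trip)
- `src/meshnet/mesh_model.py` — MeSH entity model and label modes
- `src/meshnet/corpus.py`, `gazetteer.py` — selection criteria, exclusion log, tallies
- `src/meshnet/network.py` — bipartite structure and weighted projections
- `src/meshnet/topology.py` — degree/rank/centrality reports
- `src/meshnet/ego.py` — seed + first-neighbor induced subnetworks
- `src/meshnet/synthetic.py` — seeded corpus generator and toy fixture
- `src/meshnet/pipeline.py`, `cli.py` — end-to-end orchestration and the `meshnet` CLI

See `docs/methods.md` for the modelling choices and their rationale.
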