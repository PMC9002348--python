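"""Independent brute-force oracles used to cross-check the projections.

Deliberately a different algorithm from the implementation: the package
enumerates concept pairs per article; these oracles build an inverted index
(label → set of articles carrying it) and intersect sets for every pair of
labels.  Quadratic in the number of labels/articles — fine for the small
corpora used in tests.
"""

from itertools import combinations

from meshnet.mesh_model import label as entity_label


def article_label_sets(corpus, mode="distinct"):
    return {rec.pmid: {entity_label(e, mode) for e in rec.entities} for rec in corpus.records}


def brute_concept_weights(corpus, mode="distinct"):
    """{(label_a, label_b): co-occurrence count} via pairwise set intersection."""
    sets = article_label_sets(corpus, mode)
    index = {}
    for pmid, labels in sets.items():
        for lab in labels:
            index.setdefault(lab, set()).add(pmid)
    weights = {}
    for a, b in combinations(sorted(index), 2):
        w = len(index[a] & index[b])
        if w:
            weights[(a, b)] = w
    return weights


def brute_article_weights(corpus, mode="distinct"):
    """{(pmid_a, pmid_b): shared-label count} by direct set intersection."""
    sets = article_label_sets(corpus, mode)
    weights = {}
    for a, b in combinations(sorted(sets), 2):
        w = len(sets[a] & sets[b])
        if w:
            weights[(a, b)] = w
    return weights


def graph_weights(net):
    """Edge weights of a networkx graph as a {(min, max): w} dict."""
    return {tuple(sorted((a, b), key=str)): w for a, b, w in net.edges(data="weight")}
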