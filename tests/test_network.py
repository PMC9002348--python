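from math import comb

import pytest

from meshnet.corpus import BibRecord, Corpus, apply_selection_criteria
from meshnet.mesh_model import MeshEntity
from meshnet.network import (
    build_bipartite,
    filter_min_weight,
    project_articles,
    project_concepts,
)
from meshnet.synthetic import GeneratorParams, generate_corpus

from .conftest import TOY_ARTICLE_WEIGHTS, TOY_CONCEPT_WEIGHTS
from .oracles import article_label_sets, brute_article_weights, brute_concept_weights, graph_weights


def _sorted_pairs(weights):
    return {tuple(sorted(k, key=str)): v for k, v in weights.items()}


def test_bipartite_memberships_direct_mapping():
    rec = BibRecord(pmid=1, title="t",
                    entities=[MeshEntity("Humans"), MeshEntity("Health Equity", major=True)])
    bip = build_bipartite(Corpus(records=[rec]))
    assert bip.memberships == {(1, "Humans"), (1, "*Health Equity")}


def test_bipartite_merged_mode_collapses():
    rec = BibRecord(pmid=1, title="t",
                    entities=[MeshEntity("Humans"), MeshEntity("Health Equity", major=True),
                              MeshEntity("Health Equity")])
    bip = build_bipartite(Corpus(records=[rec]), mode="merged")
    assert bip.memberships == {(1, "Humans"), (1, "Health Equity")}


def test_empty_corpus_gives_empty_graph():
    bip = build_bipartite(Corpus(records=[]))
    assert not bip.articles and not bip.memberships
    assert project_concepts(bip).number_of_nodes() == 0


def test_toy_concept_projection_matches_hand_enumeration(toy_corpus):
    net = project_concepts(build_bipartite(toy_corpus))
    assert net.number_of_nodes() == 5 and net.number_of_edges() == 7
    assert graph_weights(net) == _sorted_pairs(TOY_CONCEPT_WEIGHTS)


def test_toy_article_projection_matches_hand_enumeration(toy_corpus):
    net = project_articles(build_bipartite(toy_corpus))
    assert graph_weights(net) == _sorted_pairs(TOY_ARTICLE_WEIGHTS)


def test_single_article_gives_complete_graph_of_weight_one():
    rec = BibRecord(pmid=1, title="t", entities=[MeshEntity(f"T{i}") for i in range(6)])
    net = project_concepts(build_bipartite(Corpus(records=[rec])))
    assert net.number_of_edges() == comb(6, 2)
    assert all(w == 1 for _, _, w in net.edges(data="weight"))


def test_identical_label_sets_give_article_edge_of_full_weight():
    ents = [MeshEntity(f"T{i}") for i in range(4)]
    recs = [BibRecord(pmid=p, title="t", entities=list(ents)) for p in (1, 2)]
    net = project_articles(build_bipartite(Corpus(records=recs)))
    assert net[1][2]["weight"] == 4


def test_disjoint_articles_share_no_edge():
    recs = [BibRecord(pmid=1, title="t", entities=[MeshEntity("A")]),
            BibRecord(pmid=2, title="t", entities=[MeshEntity("B")])]
    net = project_articles(build_bipartite(Corpus(records=recs)))
    assert net.number_of_edges() == 0


@pytest.mark.parametrize("seed", range(1, 21))
def test_projections_match_bruteforce_oracle(seed):
    """Both projections agree with the inverted-index set-intersection oracle."""
    params = GeneratorParams(n_records=1 + seed % 40, vocab_size=30,
                             terms_per_record=5.0, seed=seed)
    corpus = apply_selection_criteria(generate_corpus(params))
    bip = build_bipartite(corpus)
    assert graph_weights(project_concepts(bip)) == brute_concept_weights(corpus)
    assert graph_weights(project_articles(bip)) == brute_article_weights(corpus)


@pytest.mark.parametrize("seed", range(1, 11))
def test_weight_conservation_law(seed):
    """Σ edge weights = Σₐ C(tₐ,2), and the dual for the article projection."""
    corpus = apply_selection_criteria(
        generate_corpus(GeneratorParams(n_records=30, vocab_size=40,
                                        terms_per_record=6.0, seed=seed)))
    bip = build_bipartite(corpus)
    sets = article_label_sets(corpus)
    concept_total = sum(w for _, _, w in project_concepts(bip).edges(data="weight"))
    assert concept_total == sum(comb(len(s), 2) for s in sets.values())
    label_counts = {}
    for s in sets.values():
        for lab in s:
            label_counts[lab] = label_counts.get(lab, 0) + 1
    article_total = sum(w for _, _, w in project_articles(bip).edges(data="weight"))
    assert article_total == sum(comb(c, 2) for c in label_counts.values())


def test_adding_an_article_never_decreases_weights_or_degrees(toy_corpus):
    before = project_concepts(build_bipartite(toy_corpus))
    extra = BibRecord(pmid=5, title="T5",
                      entities=[MeshEntity("Humans"), MeshEntity("Trust"),
                                MeshEntity("Health Equity")])
    after = project_concepts(
        build_bipartite(Corpus(records=toy_corpus.records + [extra])))
    for a, b, w in before.edges(data="weight"):
        assert after[a][b]["weight"] >= w
    for node in before.nodes:
        assert after.degree(node) >= before.degree(node)


def test_universal_label_is_adjacent_to_every_node():
    corpus = apply_selection_criteria(
        generate_corpus(GeneratorParams(n_records=40, vocab_size=50, universal_prob=1.0,
                                        terms_per_record=4.0, seed=11)))
    net = project_concepts(build_bipartite(corpus))
    assert net.degree("Humans") == net.number_of_nodes() - 1


def test_min_weight_filter_keeps_nodes(toy_corpus):
    net = project_concepts(build_bipartite(toy_corpus))
    filtered = filter_min_weight(net, 2)
    assert filtered.number_of_nodes() == net.number_of_nodes()
    assert {w for _, _, w in filtered.edges(data="weight")} == {2}
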