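import pytest

from meshnet.synthetic import toy_fixture


@pytest.fixture
def toy_corpus():
    """Four-article corpus whose semantic network is known by hand."""
    return toy_fixture()


# Hand enumeration of the toy corpus (A1={H,E,V}, A2={H,E,C}, A3={H,V},
# A4={H,C,T}): for each unordered concept pair, the articles carrying both.
TOY_CONCEPT_WEIGHTS = {
    ("Humans", "Health Equity"): 2,          # A1, A2
    ("Humans", "Vulnerable Populations"): 2,  # A1, A3
    ("Humans", "Culture"): 2,                # A2, A4
    ("Humans", "Trust"): 1,                  # A4
    ("Health Equity", "Vulnerable Populations"): 1,  # A1
    ("Health Equity", "Culture"): 1,         # A2
    ("Culture", "Trust"): 1,                 # A4
}

TOY_ARTICLE_WEIGHTS = {
    (1, 2): 2,  # share H, E
    (1, 3): 2,  # share H, V
    (2, 4): 2,  # share H, C
    (1, 4): 1,
    (2, 3): 1,
    (3, 4): 1,
}
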