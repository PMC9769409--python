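import pytest

from pgpscreen import fixtures


@pytest.fixture(scope="session")
def roster():
    return fixtures.load_roster()


@pytest.fixture(scope="session")
def profiles():
    return fixtures.load_trait_table()


@pytest.fixture(scope="session")
def matrix():
    return fixtures.load_inhibition_matrix()


@pytest.fixture(scope="session")
def published_scores():
    return fixtures.load_published_scores()


@pytest.fixture(scope="session")
def ranked_cards(profiles, matrix):
    from pgpscreen import bonitur

    cards = [
        bonitur.score_isolate(p, matrix.row(p.isolate_id))
        for p in profiles
        if p.isolate_id in matrix.values.index
    ]
    return bonitur.rank_isolates(cards)


@pytest.fixture(scope="session")
def cards_by_id(ranked_cards):
    return {c.isolate_id: c for c in ranked_cards}
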