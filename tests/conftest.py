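import hypothesis
import pytest

from herbscreen import Corpus, RecipeRecord, SearchTerm

hypothesis.settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50
)
hypothesis.settings.load_profile("ci")


@pytest.fixture
def search_terms():
    """Two arthritis terms (one main, one orbit) and one skin term."""
    return frozenset(
        {
            SearchTerm("crane knee wind", "arthritis", "main"),
            SearchTerm("leg pain", "arthritis", "orbit"),
            SearchTerm("bayberry sores", "skin"),
        }
    )


@pytest.fixture
def small_corpus():
    """Six recipes spanning all subset memberships.

    r1: main arthritis          r4: skin only
    r2: orbit arthritis         r5: arthritis + skin
    r3: main + orbit            r6: unrelated indication
    """
    return Corpus(
        [
            RecipeRecord("r1", {"crane knee wind"}, {"ginger", "licorice"}),
            RecipeRecord("r2", {"leg pain"}, {"ginger", "angelica"}),
            RecipeRecord("r3", {"crane knee wind", "leg pain"}, {"smilax"}),
            RecipeRecord("r4", {"bayberry sores"}, {"smilax", "licorice"}),
            RecipeRecord("r5", {"leg pain", "bayberry sores"}, {"angelica"}),
            RecipeRecord("r6", {"cough"}, {"ginger"}),
        ]
    )
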