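import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from rmavoid.model import SiteAvoidance  # noqa: E402
from rmavoid.synthetic import build_fixture_collection, default_simulation_spec  # noqa: E402


@pytest.fixture(scope="session")
def reference_fixture():
    """The package's reference synthetic collection (seed 1)."""
    return build_fixture_collection(default_simulation_spec(seed=1))


@pytest.fixture(scope="session")
def reference_results(reference_fixture):
    """Fitted analysis of the reference collection."""
    fx = reference_fixture
    model = SiteAvoidance(
        genomes=fx.genomes,
        catalogue=fx.catalogue,
        methylation_calls=fx.methylation,
        alien_fragments=fx.alien_fragments,
        alien_threshold=fx.alien_threshold,
    )
    return model.fit()


def naive_count(seq: str, word: str) -> int:
    """Independent window-by-window oracle for forward-strand IUPAC counting."""
    from rmavoid.sites import IUPAC_SETS

    sets = [IUPAC_SETS[c] for c in word.upper()]
    L = len(word)
    n = 0
    for i in range(len(seq) - L + 1):
        if all(
            (seq[i + j] in sets[j]) or (word[j].upper() == "N")
            for j in range(L)
        ):
            n += 1
    return n
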