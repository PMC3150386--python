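import pytest
from hypothesis import HealthCheck, settings

from cnvpop.kinship import kinship_matrix
from cnvpop.model import Individual, Panel, Pedigree
from cnvpop.simulate import SimConfig, simulate_dataset, simulate_pedigrees

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def trio_pedigree() -> Pedigree:
    return Pedigree(
        [
            Individual("dad", None, None, "M", "pop1"),
            Individual("mum", None, None, "F", "pop1"),
            Individual("kid", "dad", "mum", "M", "pop1"),
        ]
    )


@pytest.fixture
def cousin_pedigree() -> Pedigree:
    """Grandparental couple, two full-sib children married to unrelated
    founders, one child each: C1 and C2 are first cousins."""
    return Pedigree(
        [
            Individual("GF", None, None, "M", "pop1"),
            Individual("GM", None, None, "F", "pop1"),
            Individual("S1", "GF", "GM", "M", "pop1"),
            Individual("S2", "GF", "GM", "F", "pop1"),
            Individual("U1", None, None, "F", "pop1"),
            Individual("U2", None, None, "M", "pop1"),
            Individual("C1", "S1", "U1", "M", "pop1"),
            Individual("C2", "U2", "S2", "F", "pop1"),
        ]
    )


ISOLATE_CONFIG = SimConfig(
    n_populations=1,
    population_names=("Isolate",),
    families_per_population=15,
    family_depth=5,
    mean_children=3.0,
    immigrant_rate=0.35,
    singletons_per_population=0,
)


@pytest.fixture(scope="session")
def isolate():
    """A deeply intermarried single-population pedigree (the high-kinship
    isolate design) with its kinship matrix."""
    pedigree, panel = simulate_pedigrees(ISOLATE_CONFIG, 42)
    K = kinship_matrix(pedigree)
    return pedigree, panel, K


@pytest.fixture(scope="session")
def default_dataset():
    """One cohort simulated under the generator's default study conditions."""
    return simulate_dataset(SimConfig(), 1)
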