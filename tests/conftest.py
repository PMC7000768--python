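import numpy as np
import pytest

from cas13screen import simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def paper_scale_design():
    # 25 vlinc x 10 pairs, 7 coding x 5 pairs, 3 coding x 3 pairs
    return simulate.SimulationDesign(seed=7)


@pytest.fixture(scope="session")
def paper_scale_manifest(paper_scale_design):
    manifest, truth = simulate.simulate_manifest(paper_scale_design)
    return manifest


@pytest.fixture(scope="session")
def small_design():
    return simulate.SimulationDesign(
        n_vlinc=2,
        pairs_per_vlinc=10,
        coding_pairs=(3,),
        drugs={"etoposide": simulate.DrugModel(0.5, 1)},
        effects={("vlinc01", "etoposide"): -2.0},
        population=50_000,
        depth=100_000,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_screen(small_design):
    manifest, truth = simulate.simulate_manifest(small_design)
    screen = simulate.simulate_screen_counts(small_design, manifest)
    return small_design, manifest, screen
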