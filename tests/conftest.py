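"""Shared fixtures: a small seeded transcriptome/screen and the reference tables."""

import pytest

from y2hseq.io import load_paper_fixture
from y2hseq.simulate import (
    ScreenSimulationParams,
    simulate_library,
    simulate_screen,
    simulate_transcriptome,
)


@pytest.fixture(scope="session")
def t3():
    return load_paper_fixture("T3")


@pytest.fixture(scope="session")
def t4():
    return load_paper_fixture("T4")


@pytest.fixture(scope="session")
def small_transcriptome():
    """150 random genes with transcripts, CDS coordinates and proteins."""
    return simulate_transcriptome(150, seed=7)


@pytest.fixture(scope="session")
def small_screen(small_transcriptome):
    """A seeded 150-gene screen pair with three spiked interactors."""
    annotations, transcripts = small_transcriptome
    interactors = {"SIM00010": 50.0, "SIM00050": 100.0, "SIM00090": 500.0}
    params = ScreenSimulationParams(
        n_genes=150,
        interactor_set=interactors,
        total_fragments_bait=150_000,
        total_fragments_empty=150_000,
        seed=7,
    )
    clones = simulate_library(params, annotations, seed=7)
    screen = simulate_screen(clones, params, seed=8)
    return screen, clones, annotations, transcripts
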