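"""Shared fixtures: one standard-profile recombination run, one deep run
(for flank-coverage statistics), and one ecotype panel, reused across the
suite to keep the total runtime in minutes."""

from __future__ import annotations

import numpy as np
import pytest

from mitorec import pipeline as pl
from mitorec import synthetic_data as sd

SEED = 11


@pytest.fixture(scope="session")
def msh1_fixture() -> pl.Msh1Fixture:
    return pl.simulate_msh1(100_000, seed=SEED, profile="standard")


@pytest.fixture(scope="session")
def msh1_results(msh1_fixture) -> pl.Msh1Results:
    return pl.analyze_recombination(msh1_fixture.truth.genome, msh1_fixture.libraries)


@pytest.fixture(scope="session")
def deep_fixture() -> pl.Msh1Fixture:
    return pl.simulate_msh1(100_000, seed=SEED, profile="deep")


@pytest.fixture(scope="session")
def deep_results(deep_fixture) -> pl.Msh1Results:
    return pl.analyze_recombination(deep_fixture.truth.genome, deep_fixture.libraries)


@pytest.fixture(scope="session")
def panel_fixture() -> pl.PanelFixture:
    return pl.simulate_panel(seed=SEED)


@pytest.fixture(scope="session")
def panel_results(panel_fixture) -> pl.PanelResults:
    return pl.analyze_panel(
        panel_fixture.truth.reference.genome, panel_fixture.libraries
    )


@pytest.fixture(scope="session")
def truth_match(msh1_results, msh1_fixture) -> dict[str, str]:
    return pl.match_to_truth(msh1_results, msh1_fixture.truth)


@pytest.fixture(scope="session")
def deep_truth_match(deep_results, deep_fixture) -> dict[str, str]:
    return pl.match_to_truth(deep_results, deep_fixture.truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def small_reference(seed: int = 0, genome_length: int = 30_000, n: int = 4):
    """A compact reference with a handful of planted pairs, for unit tests."""
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n):
        specs.append(
            sd.RepeatSpec(
                name=f"U{i + 1}",
                length=int(rng.integers(80, 240)),
                identity=float(rng.uniform(90, 98)),
                donor=int(rng.integers(1, 3)),
                fate_class="I" if i % 2 == 0 else "II",
            )
        )
    return sd.build_reference(genome_length, specs, seed, n_decoys=2)
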