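"""Shared fixtures: the planted strain panel (expensive, session-scoped)
and small hand-built catalogs/kinetics used across modules."""

import numpy as np
import pandas as pd
import pytest

from oligopm.catalog import (
    NEGATIVE_WELL,
    POSITIVE_WELL,
    PlateLayout,
    WellContent,
    default_peptides,
    well_names,
)
from oligopm.scoring import build_profile_matrix
from oligopm.simulate import KineticSimConfig, paper_scenario, simulate_plate_set


def make_tiny_catalog(n_substrates: int = 3, plate_id: str = "PM6") -> list[PlateLayout]:
    """One plate with controls at A1/A2 and the first n default peptides."""
    peps = default_peptides()[:n_substrates]
    wells = {
        NEGATIVE_WELL: WellContent("negative_control"),
        POSITIVE_WELL: WellContent("positive_control"),
    }
    free = [w for w in well_names() if w not in (NEGATIVE_WELL, POSITIVE_WELL)]
    for well, pep in zip(free, peps):
        wells[well] = WellContent("substrate", pep)
    return [PlateLayout(plate_id, wells)]


def make_tiny_kinetics(
    levels_by_strain: dict[str, list[int]],
    catalog: list[PlateLayout],
    noise_sd: float = 0.0,
    replicates: int = 1,
    seed: int = 0,
    **cfg_kwargs,
) -> tuple[pd.DataFrame, pd.DataFrame, KineticSimConfig]:
    """Simulate a small plate set from per-strain level vectors."""
    names = [p.display_name for _, p in catalog[0].substrates()]
    planted = pd.DataFrame(
        levels_by_strain, index=names[: len(next(iter(levels_by_strain.values())))]
    ).T
    planted.index.name = "strain_id"
    cfg = KineticSimConfig(
        planted_levels=planted,
        noise_sd=noise_sd,
        replicates=replicates,
        seed=seed,
        **cfg_kwargs,
    )
    kinetics, truth = simulate_plate_set(cfg, catalog)
    return kinetics, truth, cfg


@pytest.fixture(scope="session")
def tiny_catalog():
    return make_tiny_catalog()


@pytest.fixture(scope="session")
def paper_like():
    """Zero-noise planted panel: (scenario, truth levels, recovered matrix)."""
    scenario = paper_scenario("paper_like", noise_sd=0.0, replicates=2, seed=1)
    kinetics, truth = simulate_plate_set(scenario.config, scenario.catalog)
    matrix = build_profile_matrix(kinetics, scenario.catalog)
    return scenario, truth, matrix


@pytest.fixture(scope="session")
def noisy_paper_like():
    """Same panel at 5 % signal noise (of the glutamine amplitude), 3 replicates."""
    scenario = paper_scenario("paper_like", noise_sd=10.0, replicates=3, seed=1)
    kinetics, truth = simulate_plate_set(scenario.config, scenario.catalog)
    matrix = build_profile_matrix(kinetics, scenario.catalog)
    return scenario, truth, matrix


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
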