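"""Shared fixtures: small synthetic worlds and model-frame builders."""

from __future__ import annotations

import pandas as pd
import pytest

from martendyn import SimConfig, build_world


@pytest.fixture(scope="session")
def small_world():
    """A reduced study system: quick to build, still multi-municipality."""
    cfg = SimConfig(
        n_transects=150,
        n_municipalities=8,
        region_width_km=80.0,
        region_height_km=120.0,
        n_spruce_patches=120,
        n_agri_patches=90,
        seed=42,
    )
    return build_world(cfg)


@pytest.fixture(scope="session")
def default_world():
    """The full default study system (593 transects, 19 municipalities)."""
    return build_world(SimConfig(seed=0))


def make_abundance_frame(n: int, delta, theta: float, year_sd: float, seed: int) -> tuple[pd.DataFrame, dict]:
    """Model-ready NB count data simulated directly from the abundance GLMM."""
    from martendyn import simulate_abundance_dataset

    df, truth = simulate_abundance_dataset(
        n, true_delta=delta, nb_dispersion=theta, year_effect_sd=year_sd, seed=seed
    )
    return df, {"delta": truth["delta"], "theta": theta, "year_effects": truth["year_effects"]}
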