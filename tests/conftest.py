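"""Shared synthetic datasets; generated once per session to keep the suite fast."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from circadiv import ElongationModel, LightProfile, SizeControlParams
from circadiv.simulate import SimConfig, generate_dataset


@pytest.fixture(scope="session")
def default_params() -> SizeControlParams:
    return SizeControlParams()


@pytest.fixture(scope="session")
def clockdel_constant():
    """Clock-deletion-like dataset under constant light (~1,000 cells)."""
    cfg = SimConfig(T=120.0, n_lineages=120, dt_acq=0.75, seed=5)
    return generate_dataset(cfg, "clockdel_constant")


@pytest.fixture(scope="session")
def wt_constant():
    """Wild-type-like dataset under constant light (~1,000 cells)."""
    cfg = SimConfig(T=120.0, n_lineages=120, dt_acq=0.75, seed=5)
    return generate_dataset(cfg, "WT_constant")


@pytest.fixture(scope="session")
def wt_ld():
    cfg = SimConfig(T=120.0, n_lineages=120, dt_acq=1.0, seed=9)
    return generate_dataset(cfg, "WT_LD")


@pytest.fixture(scope="session")
def clockdel_ld():
    cfg = SimConfig(T=120.0, n_lineages=120, dt_acq=1.0, seed=9)
    return generate_dataset(cfg, "clockdel_LD")


@pytest.fixture()
def tiny_cells() -> pd.DataFrame:
    """Hand-written six-cell table for I/O and regression edge cases."""
    return pd.DataFrame(
        {
            "cell_id": [0, 1, 2, 3, 4, 5],
            "lineage_id": [0, 0, 1, 1, 2, 2],
            "parent_id": [-1, 0, -1, 2, -1, 4],
            "condition": ["custom"] * 6,
            "birth_time_h": [0.0, 10.0, 0.75, 11.0, 1.5, 12.0],
            "division_time_h": [10.0, 21.0, 11.0, 22.5, 12.0, np.nan],
            "birth_length_um": [3.0, 3.2, 2.8, 3.1, 3.3, 2.9],
            "division_length_um": [6.1, 6.3, 5.9, 6.2, 6.4, np.nan],
            "censored": [0, 0, 0, 0, 0, 1],
        }
    )


@pytest.fixture(scope="session")
def constant_profile() -> LightProfile:
    return LightProfile(mode="constant", A=15.0)


@pytest.fixture(scope="session")
def graded_profile() -> LightProfile:
    return LightProfile(mode="graded_LD", A=15.0, TL=12.0)


@pytest.fixture(scope="session")
def flat_elongation() -> ElongationModel:
    return ElongationModel(alpha_bar=0.06, epsilon=0.0)
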