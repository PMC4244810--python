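"""Shared fixtures: small synthetic experiments and single-founder builders."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from microlapse.config import AnalysisConfig
from microlapse.simulate import FateRecord, PositionRenderer, SimulationParams

# segmentation warnings on deliberately blank frames are part of the contract
warnings.filterwarnings("ignore", message="frame segmented empty")


@pytest.fixture
def cfg() -> AnalysisConfig:
    return AnalysisConfig(seed=0)


@pytest.fixture
def small_params() -> SimulationParams:
    """A fast desk-scale experiment: 2x2 grid, 96 px fields, 7 frames."""
    return SimulationParams(
        seed=5, grid_shape=(2, 2), field_shape=(96, 96), horizon=12.0, dt=2.0,
        founders_per_field_mean=2.0, min_separation=20.0, margin=15,
    )


def make_record(founder_id: int = 0, position: str = "r0c0",
                centroid=(100.0, 100.0), a0: float = 30.0, fate: str = "grower",
                morphology: str = "S", lag: float = 2.0, mu_max: float = 0.5,
                ymax: float = 9.0, pi_positive_time=None, hole_fraction=None,
                shape_seed: int = 1, **kw) -> FateRecord:
    if hole_fraction is None:
        hole_fraction = 0.15 if morphology == "R" else 0.0
    return FateRecord(
        founder_id=founder_id, position=position, centroid=centroid, a0=a0,
        fate=fate, morphology=morphology,
        lag=lag if fate == "grower" else 0.0,
        mu_max=mu_max if fate == "grower" else 0.0,
        ymax=ymax, pi_positive_time=pi_positive_time,
        hole_fraction=hole_fraction, shape_seed=shape_seed, **kw,
    )


@pytest.fixture
def record_factory():
    return make_record


def render_position_stacks(records, params, *, noise_free=False, seed=0):
    """Render brightfield and PI stacks for one position."""
    if noise_free:
        params = params.model_copy(deep=True)
        params.intensity.background_sd = 0.0
        params.intensity.pi_background_sd = 0.0
    rend = PositionRenderer(records, params)
    bf, pi = [], []
    for i, t in enumerate(params.frame_times):
        bf.append(rend.render(float(t), "brightfield", seed=seed + 2 * i)[0])
        pi.append(rend.render(float(t), "pi", seed=seed + 2 * i + 1)[0])
    return bf, pi, rend


@pytest.fixture
def render_stacks():
    return render_position_stacks
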