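"""Shared fixtures: canonical environments and pipeline helpers."""

from __future__ import annotations

import numpy as np
import pytest

import persisterpop as pp


@pytest.fixture
def gaps() -> pp.RateGaps:
    return pp.presets.ecoli_gaps()


@pytest.fixture
def growth_env() -> pp.EnvironmentParams:
    return pp.presets.ecoli_growth()


@pytest.fixture
def stress_env() -> pp.EnvironmentParams:
    return pp.presets.ecoli_stress()


def steady_state(env: pp.EnvironmentParams, total: float = 1e8) -> pp.PopulationState:
    """Population of size ``total`` sitting at the exact steady-state
    structure of ``env`` (dominant-eigenvector composition)."""
    _, ratio_np = pp.dominant_eigenpair(env)
    if np.isinf(ratio_np):
        return pp.PopulationState(0.0, total, 0.0)
    n = total * ratio_np / (1.0 + ratio_np)
    return pp.PopulationState(0.0, n, total - n)


def shift_pipeline(a: float, b: float, noise: pp.NoiseModel | None = None,
                   sampling: int = 40) -> pp.SwitchingInference:
    """Full measurement pipeline with known switching rates: simulate both
    shift experiments from steady state, fit the post-shift segments,
    locate the transitions and invert for (a, b)."""
    env_g = pp.presets.ecoli_growth(a, b)
    env_s = pp.presets.ecoli_stress(a, b)
    gaps = pp.presets.ecoli_gaps()
    if noise is None:
        noise = pp.NoiseModel(kind="none")

    segments = {}
    for pre, post, cond in ((env_g, env_s, "stress"), (env_s, env_g, "growth")):
        table = pp.generate_shift_curves(
            pre, post, 15.0, 15.0, steady_state(pre), sampling=sampling, noise=noise
        )
        df = table.frame
        seg = df[df["time_h"] >= 15.0]
        segments[cond] = (seg["time_h"].to_numpy() - 15.0, seg["cfu_total"].to_numpy())
    return pp.switching_rates_from_curves(segments["stress"], segments["growth"], gaps)
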