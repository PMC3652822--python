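"""Synthetic CFU-curve generator.

Produces count tables for the two canonical experiment designs — a
growth/stress shift (biphasic kill or regrowth curves) and a periodic
environment — by sampling the deterministic model and corrupting the
counts with a plating-noise model.  The default noise is multiplicative
lognormal with sigma = 0.1 on log10 counts, the typical spread of CFU
plate counts; a Poisson colony-count model and noiseless output are also
available.  All randomness flows from the single mandatory seed recorded
in the table metadata, so identical seeds give identical tables.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dynamics import PopulationState, Trajectory, simulate_protocol
from .params import EnvironmentParams, ValidationError
from .periodic import CycleSpec
from .tables import SCHEMA_VERSION, CountTable

__all__ = [
    "NoiseModel",
    "generate_constant_curve",
    "generate_shift_curves",
    "generate_periodic_curves",
]


@dataclass(frozen=True)
class NoiseModel:
    """Observation noise applied to the deterministic counts.

    ``lognormal``: multiply each count by 10**eps, eps ~ N(0, sigma^2)
    (sigma on the log10 scale).  ``poisson_cfu``: emulate plating a
    ``plated_fraction`` dilution and counting colonies, count ~
    Poisson(N * f) / f.  ``none``: exact model output.
    """

    kind: str = "lognormal"
    sigma: float = 0.1
    plated_fraction: float = 1e-6
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("lognormal", "poisson_cfu", "none"):
            raise ValidationError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValidationError("sigma must be nonnegative")
        if not (0 < self.plated_fraction <= 1):
            raise ValidationError("plated_fraction must be in (0, 1]")
        if self.kind != "none" and self.seed is None:
            raise ValidationError("a seed is mandatory for stochastic noise models")

    def apply(self, counts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "none":
            return counts.copy()
        if self.kind == "lognormal":
            eps = rng.normal(0.0, self.sigma, size=counts.shape)
            return counts * 10.0**eps
        plated = rng.poisson(counts * self.plated_fraction)
        return plated / self.plated_fraction


def _table_from_trajectory(
    traj: Trajectory, noise: NoiseModel, n_replicates: int, metadata: dict
) -> CountTable:
    rng = np.random.default_rng(noise.seed if noise.seed is not None else 0)
    frames = []
    for rep in range(n_replicates):
        n_obs = noise.apply(traj.n, rng)
        p_obs = noise.apply(traj.p, rng)
        frames.append(
            pd.DataFrame(
                {
                    "time_h": traj.times,
                    "cfu_total": n_obs + p_obs,
                    "cfu_normal": n_obs,
                    "cfu_persister": p_obs,
                    "replicate": rep,
                }
            )
        )
    meta = dict(metadata)
    meta["noise"] = asdict(noise)
    meta["schema_version"] = SCHEMA_VERSION
    return CountTable(frame=pd.concat(frames, ignore_index=True), metadata=meta)


def _env_meta(env: EnvironmentParams) -> dict:
    return {
        "label": env.label,
        "mu_n": env.rates.mu_n,
        "mu_p": env.rates.mu_p,
        "a": env.switching.a,
        "b": env.switching.b,
        "carrying_capacity": env.carrying_capacity,
    }


def generate_constant_curve(
    env: EnvironmentParams,
    t_end: float,
    state0: PopulationState,
    sampling: int = 30,
    noise: NoiseModel = NoiseModel(kind="none"),
    n_replicates: int = 1,
) -> CountTable:
    """Synthetic count table for a single constant environment (e.g. one
    kill curve without the preceding growth phase)."""
    if sampling < 2:
        raise ValidationError("sampling must be >= 2 points")
    traj = simulate_protocol([(env, t_end)], state0, samples_per_phase=sampling)
    meta = {
        "design": "constant",
        "env": _env_meta(env),
        "t_end": t_end,
        "state0": {"t": state0.t, "n": state0.n, "p": state0.p},
        "sampling": sampling,
    }
    return _table_from_trajectory(traj, noise, n_replicates, meta)


def generate_shift_curves(
    env_pre: EnvironmentParams,
    env_post: EnvironmentParams,
    t_pre: float,
    t_post: float,
    state0: PopulationState,
    sampling: int = 30,
    noise: NoiseModel = NoiseModel(kind="none"),
    n_replicates: int = 1,
) -> CountTable:
    """Synthetic shift experiment: ``t_pre`` hours in ``env_pre`` followed
    by ``t_post`` hours in ``env_post``, ``sampling`` observation times
    per phase.  Noiseless means come from the exact piecewise solution;
    noise is applied independently per observation and replicate."""
    if sampling < 2:
        raise ValidationError("sampling must be >= 2 points per phase")
    traj = simulate_protocol(
        [(env_pre, t_pre), (env_post, t_post)], state0, samples_per_phase=sampling
    )
    meta = {
        "design": "shift",
        "env_pre": _env_meta(env_pre),
        "env_post": _env_meta(env_post),
        "t_pre": t_pre,
        "t_post": t_post,
        "state0": {"t": state0.t, "n": state0.n, "p": state0.p},
        "sampling": sampling,
        "shift_time": state0.t + t_pre,
    }
    return _table_from_trajectory(traj, noise, n_replicates, meta)


def generate_periodic_curves(
    spec: CycleSpec,
    n_cycles: int,
    state0: PopulationState,
    sampling: int = 20,
    noise: NoiseModel = NoiseModel(kind="none"),
    n_replicates: int = 1,
) -> CountTable:
    """Synthetic periodic-environment experiment over ``n_cycles`` cycles
    (``sampling`` observations per phase)."""
    if n_cycles < 1:
        raise ValidationError("n_cycles must be >= 1")
    if sampling < 2:
        raise ValidationError("sampling must be >= 2 points per phase")
    protocol = []
    for _ in range(n_cycles):
        if spec.t_g > 0:
            protocol.append((spec.env_g, spec.t_g))
        if spec.t_s > 0:
            protocol.append((spec.env_s, spec.t_s))
    traj = simulate_protocol(protocol, state0, samples_per_phase=sampling)
    meta = {
        "design": "periodic",
        "env_g": _env_meta(spec.env_g),
        "env_s": _env_meta(spec.env_s),
        "t_g": spec.t_g,
        "t_s": spec.t_s,
        "n_cycles": n_cycles,
        "state0": {"t": state0.t, "n": state0.n, "p": state0.p},
        "sampling": sampling,
    }
    return _table_from_trajectory(traj, noise, n_replicates, meta)
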