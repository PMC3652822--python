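"""Exact dynamics of the linear two-state model and its carrying-capacity
extension.

The model: normal cells ``n`` and persisters ``p`` obey

    dn/dt = mu_n n - a n + b p
    dp/dt = mu_p p + a n - b p

which is linear, ``x' = M x`` with the Metzler matrix ``M`` returned by
:func:`rate_matrix`.  :func:`propagate_exact` evaluates the matrix
exponential analytically (2x2 closed form, with a series fallback when
the eigenvalues nearly coincide) and serves as the ground-truth oracle
for every approximation elsewhere in the package.

With a finite carrying capacity ``K`` the positive (growth) terms are
throttled by ``(1 - N/K)`` where ``N = n + p``; that variant is no
longer linear and is integrated numerically by :func:`integrate_capacity`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .params import EnvironmentParams, ValidationError

__all__ = [
    "PopulationState",
    "Trajectory",
    "rate_matrix",
    "propagate_exact",
    "propagator_matrix",
    "integrate_capacity",
    "dominant_eigenpair",
    "simulate_protocol",
]

# Oracle-grade integrator tolerances (the numerical route is itself used
# as a reference in tests).
ORACLE_RTOL = 1e-10
ORACLE_ATOL = 1e-12

# Relative eigenvalue gap below which the closed-form propagator switches
# to a scaled Taylor series to avoid catastrophic cancellation.
_DEGENERACY_EPS = 1e-10


@dataclass(frozen=True)
class PopulationState:
    """Snapshot ``(t, n, p)`` of both subpopulations (t in hours)."""

    t: float
    n: float
    p: float

    def __post_init__(self) -> None:
        for name in ("t", "n", "p"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValidationError(f"PopulationState.{name} must be finite, got {v!r}")
        if self.n < 0 or self.p < 0:
            raise ValidationError(
                f"population counts must be nonnegative, got n={self.n}, p={self.p}"
            )

    @property
    def total(self) -> float:
        return self.n + self.p

    @property
    def ratio_np(self) -> float:
        """Subpopulation ratio n/p (inf when p == 0)."""
        return self.n / self.p if self.p > 0 else math.inf

    @property
    def ratio_pn(self) -> float:
        """Subpopulation ratio p/n (inf when n == 0)."""
        return self.p / self.n if self.n > 0 else math.inf

    @property
    def persister_fraction(self) -> float:
        return self.p / self.total if self.total > 0 else math.nan

    def as_vector(self) -> np.ndarray:
        return np.array([self.n, self.p], dtype=float)


@dataclass
class Trajectory:
    """Time series of population states, with optional per-sample phase
    labels and the times of environment changes (``phase_boundaries``)."""

    times: np.ndarray
    n: np.ndarray
    p: np.ndarray
    phase_labels: list[str] = field(default_factory=list)
    phase_boundaries: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if not (self.times.shape == self.n.shape == self.p.shape):
            raise ValidationError("times, n, p must have identical shapes")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValidationError("trajectory times must be strictly increasing")
        if self.phase_labels and len(self.phase_labels) != self.times.size:
            raise ValidationError("phase_labels must match the number of samples")

    @property
    def total(self) -> np.ndarray:
        return self.n + self.p

    def __len__(self) -> int:
        return int(self.times.size)

    def state(self, i: int) -> PopulationState:
        return PopulationState(
            float(self.times[i]), max(float(self.n[i]), 0.0), max(float(self.p[i]), 0.0)
        )

    @property
    def final(self) -> PopulationState:
        return self.state(len(self) - 1)


def rate_matrix(env: EnvironmentParams) -> np.ndarray:
    """Rate matrix ``M`` of the linear model, ordering ``[n, p]``:
    ``M = [[mu_n - a, b], [a, mu_p - b]]``."""
    mu_n, mu_p = env.rates.mu_n, env.rates.mu_p
    a, b = env.switching.a, env.switching.b
    return np.array([[mu_n - a, b], [a, mu_p - b]], dtype=float)


def _expm2(M: np.ndarray, dt: float) -> np.ndarray:
    """Closed-form ``exp(M dt)`` for a real 2x2 Metzler matrix with real
    spectrum (discriminant = (gap)^2 + 4ab >= 0 for this model).

    Splits M = m I + D (D traceless, eigenvalues +-q) and uses the
    spectral projectors

        exp(M dt) = e^{(m+q) dt} (q I + D)/(2q) + e^{(m-q) dt} (q I - D)/(2q).

    The diagonal entries of ``q I +- D`` are evaluated via
    ``q - |D00|^2/q ... = M01 M10 / (q + |D00|)`` when direct subtraction
    would cancel, so every projector entry is an exact nonnegative
    quantity and the result keeps full relative precision even when one
    eigencomponent is exponentially small.  Near-degenerate spectra
    (q dt tiny) use the series form instead.
    """
    if dt == 0.0:
        return np.eye(2)
    m = 0.5 * (M[0, 0] + M[1, 1])
    d = 0.5 * (M[0, 0] - M[1, 1])  # = D00 = -D11
    off = float(M[0, 1] * M[1, 0])  # = b*a >= 0
    q2 = d * d + off
    if q2 < 0:
        from scipy.linalg import expm

        return expm(M * dt)
    q = math.sqrt(q2)
    x = q * dt
    if x < 1e-6:
        # sinh(x)/x and cosh(x) by series: accurate to ~1e-26 at x=1e-6
        x2 = x * x
        sinch = 1.0 + x2 / 6.0 + x2 * x2 / 120.0
        cosh = 1.0 + x2 / 2.0 + x2 * x2 / 24.0
        D = np.array([[d, M[0, 1]], [M[1, 0], -d]])
        return math.exp(m * dt) * (cosh * np.eye(2) + sinch * dt * D)
    # cancellation-safe q + d and q - d: q^2 - d^2 = off
    if d >= 0:
        q_plus_d = q + d
        q_minus_d = off / q_plus_d if q_plus_d > 0 else 0.0
    else:
        q_minus_d = q - d
        q_plus_d = off / q_minus_d if q_minus_d > 0 else 0.0
    e1 = math.exp((m + q) * dt)
    e2 = math.exp((m - q) * dt)
    diff = 2.0 * math.exp(m * dt) * math.sinh(x)  # = e1 - e2, cancellation-free
    inv2q = 0.5 / q
    return np.array(
        [
            [
                (e1 * q_plus_d + e2 * q_minus_d) * inv2q,
                diff * M[0, 1] * inv2q,
            ],
            [
                diff * M[1, 0] * inv2q,
                (e1 * q_minus_d + e2 * q_plus_d) * inv2q,
            ],
        ]
    )


def propagator_matrix(env: EnvironmentParams, dt: float) -> np.ndarray:
    """Exact propagator ``exp(M dt)`` for one environment over ``dt`` hours."""
    if dt < 0:
        raise ValidationError(f"dt must be nonnegative, got {dt}")
    if env.has_capacity:
        raise ValidationError(
            "exact propagation requires infinite carrying capacity; "
            "use integrate_capacity for finite K"
        )
    return _expm2(rate_matrix(env), dt)


def propagate_exact(
    env: EnvironmentParams, state0: PopulationState, dt: float
) -> PopulationState:
    """Advance ``state0`` by ``dt`` hours under a constant environment using
    the analytic solution of the linear model."""
    P = propagator_matrix(env, dt)
    n, p = P @ state0.as_vector()
    return PopulationState(state0.t + dt, max(float(n), 0.0), max(float(p), 0.0))


def sample_exact(
    env: EnvironmentParams, state0: PopulationState, t_grid: Sequence[float]
) -> Trajectory:
    """Exact solution sampled on ``t_grid`` (absolute times >= state0.t)."""
    t_grid = np.asarray(t_grid, dtype=float)
    M = rate_matrix(env)
    ns, ps = [], []
    x0 = state0.as_vector()
    for t in t_grid:
        x = _expm2(M, float(t) - state0.t) @ x0
        ns.append(max(float(x[0]), 0.0))
        ps.append(max(float(x[1]), 0.0))
    return Trajectory(t_grid, np.array(ns), np.array(ps), [env.label] * t_grid.size)


def _capacity_rhs(env: EnvironmentParams):
    mu_n, mu_p = env.rates.mu_n, env.rates.mu_p
    a, b = env.switching.a, env.switching.b
    K = env.carrying_capacity

    def rhs(t, x):
        n, p = x
        crowd = 1.0 - (n + p) / K
        # only positive net rates are growth terms and feel the capacity
        gn = mu_n * crowd if mu_n > 0 else mu_n
        gp = mu_p * crowd if mu_p > 0 else mu_p
        return [gn * n - a * n + b * p, gp * p + a * n - b * p]

    return rhs


def integrate_capacity(
    env: EnvironmentParams,
    state0: PopulationState,
    t_grid: Sequence[float],
    rtol: float = ORACLE_RTOL,
    atol: float = ORACLE_ATOL,
) -> Trajectory:
    """Numerically integrate the carrying-capacity model on ``t_grid``
    (absolute times, increasing, starting at or after ``state0.t``).

    Growth terms (positive net rates) are multiplied by ``(1 - N/K)``;
    death and switching terms are untouched.  As ``K -> inf`` this
    reduces to the linear model.
    """
    if not env.has_capacity:
        # K = inf: the model is linear, use the exact route on the grid
        return sample_exact(env, state0, t_grid)
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size < 1 or (t_grid.size > 1 and not np.all(np.diff(t_grid) > 0)):
        raise ValidationError("t_grid must be non-empty and strictly increasing")
    if t_grid[0] < state0.t:
        raise ValidationError("t_grid must start at or after state0.t")
    sol = solve_ivp(
        _capacity_rhs(env),
        (state0.t, float(t_grid[-1])),
        state0.as_vector(),
        t_eval=t_grid,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"capacity integration failed: {sol.message}")
    n = np.maximum(sol.y[0], 0.0)
    p = np.maximum(sol.y[1], 0.0)
    return Trajectory(t_grid, n, p, [env.label] * t_grid.size)


def dominant_eigenpair(env: EnvironmentParams) -> tuple[float, float]:
    """Long-time growth rate and population structure in a constant
    environment.

    Returns ``(rate, ratio_np)``: the largest-real-part eigenvalue of the
    rate matrix (the steady-state per-capita rate of the total population)
    and the ``n/p`` ratio of its eigenvector (the steady-state structure;
    ``inf`` if the persister component vanishes).
    """
    if env.has_capacity:
        raise ValidationError("dominant_eigenpair requires infinite carrying capacity")
    M = rate_matrix(env)
    m = 0.5 * (M[0, 0] + M[1, 1])
    q = math.sqrt(max(0.25 * (M[0, 0] - M[1, 1]) ** 2 + M[0, 1] * M[1, 0], 0.0))
    lam = m + q
    # eigenvector (n, p): use whichever row gives the better-conditioned
    # quotient (the one whose diagonal sits far from lam)
    d0 = lam - M[0, 0]
    d1 = lam - M[1, 1]
    if M[1, 0] > 0 and (d1 >= d0 or M[0, 1] == 0):
        ratio = d1 / M[1, 0]  # second row: a n = (lam - M11) p
    elif M[0, 1] > 0:
        ratio = M[0, 1] / d0 if d0 > 0 else math.inf  # first row: b p = (lam - M00) n
    else:
        # no switching: phenotypes decouple, structure is pure-n or pure-p
        ratio = math.inf if M[0, 0] >= M[1, 1] else 0.0
    return lam, ratio


def simulate_protocol(
    envs: Sequence[tuple[EnvironmentParams, float]],
    state0: PopulationState,
    samples_per_phase: int = 200,
) -> Trajectory:
    """Piecewise-constant environment protocol.

    ``envs`` is a sequence of ``(environment, duration_hours)`` phases;
    ``(n, p)`` is continuous across phase boundaries.  Each phase is
    sampled on ``samples_per_phase`` points (endpoint of each phase
    included); boundary times are recorded in ``phase_boundaries``.
    Phases with a finite carrying capacity are integrated numerically,
    the rest use the exact propagator.
    """
    envs = list(envs)
    if not envs:
        raise ValidationError("protocol must contain at least one phase")
    if samples_per_phase < 2:
        raise ValidationError("samples_per_phase must be >= 2")
    for env, dur in envs:
        if not dur > 0:
            raise ValidationError(f"phase durations must be positive, got {dur}")

    times: list[np.ndarray] = []
    ns: list[np.ndarray] = []
    ps: list[np.ndarray] = []
    labels: list[str] = []
    boundaries: list[float] = []
    state = state0
    for k, (env, dur) in enumerate(envs):
        # drop the first grid point of later phases (duplicate of boundary)
        grid = state.t + np.linspace(0.0, dur, samples_per_phase)
        if env.has_capacity:
            seg = integrate_capacity(env, state, grid)
        else:
            seg = sample_exact(env, state, grid)
        sl = slice(1, None) if k > 0 else slice(None)
        times.append(seg.times[sl])
        ns.append(seg.n[sl])
        ps.append(seg.p[sl])
        labels.extend([env.label] * len(seg.times[sl]))
        state = seg.final
        if k < len(envs) - 1:
            boundaries.append(state.t)
    return Trajectory(
        np.concatenate(times),
        np.concatenate(ns),
        np.concatenate(ps),
        labels,
        boundaries,
    )
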