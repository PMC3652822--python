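"""Small-switching-rate approximation layer.

The subpopulation ratio of the linear two-state model obeys a Riccati
equation.  Writing the ratio in its *oriented* form r = majority/minority
(n/p in a growth medium, p/n under stress), with g the rate gap in
favour of the majority, s_out the switching rate out of the majority
phenotype and s_in the rate into it,

    dr/dt = -s_out r^2 + (g - s_out + s_in) r + s_in

whose two real fixed points are the roots of the quadratic.  When the
switching rates are small compared to g, the unstable root collapses to
zero and the stable root to g/s_out, and the equation reduces to the
logistic form  dr/dt = g r (1 - r / r*) with r* = g/s_out.  Everything
in this module — steady-state structure, relaxation, time-dependent and
averaged growth rates, and the double-exponential total population —
follows from that reduction.  The exact propagator in
:mod:`persisterpop.dynamics` is the oracle that gates each formula.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .params import (
    EnvironmentParams,
    RateGaps,
    SwitchingRates,
    ValidationError,
    warn_if_not_small_switching,
)

__all__ = [
    "RatioFixedPoints",
    "SteadyStateStructure",
    "oriented_parameters",
    "ratio_fixed_points",
    "steady_state_structure",
    "stationary_phase_fraction",
    "logistic_ratio",
    "average_subpop_growth",
    "total_double_exponential",
    "average_total_growth",
]


@dataclass(frozen=True)
class RatioFixedPoints:
    """Roots of the oriented-ratio quadratic: ``r_unstable`` (lower,
    possibly negative) and ``r_stable`` (upper, always positive)."""

    r_unstable: float
    r_stable: float


@dataclass(frozen=True)
class SteadyStateStructure:
    """Leading-order steady state in one environment.

    ``ratio_star``: stable majority/minority ratio (n/p in growth, p/n in
    stress); ``persister_fraction``: p/(n+p) at the steady state;
    ``relaxation_rate``: rate of approach of the ratio to its steady
    state (1/h); ``effective_rate``: long-time per-capita rate of the
    total population (1/h), ``mu_n - a`` in growth and ``-(kappa_p + b)``
    under stress.
    """

    ratio_star: float
    persister_fraction: float
    relaxation_rate: float
    effective_rate: float


def oriented_parameters(env: EnvironmentParams) -> tuple[float, float, float, bool]:
    """Return ``(g, s_out, s_in, majority_is_normal)`` for the oriented
    ratio of ``env``: the rate gap in favour of the majority phenotype,
    the switching rates out of and into it, and the orientation flag.

    Normal cells are the majority when ``mu_n >= mu_p`` (growth medium);
    persisters when ``mu_p > mu_n`` (stress).
    """
    r, sw = env.rates, env.switching
    if r.mu_n >= r.mu_p:
        return r.mu_n - r.mu_p, sw.a, sw.b, True
    return r.mu_p - r.mu_n, sw.b, sw.a, False


def ratio_fixed_points(env: EnvironmentParams) -> RatioFixedPoints:
    """Exact fixed points of the oriented-ratio equation.

    Roots of ``-s_out r^2 + (g - s_out + s_in) r + s_in = 0`` computed with
    the cancellation-safe q-scheme.  The discriminant
    ``(g - s_out + s_in)^2 + 4 s_out s_in`` is nonnegative for any
    nonnegative switching rates, so the roots are always real.
    """
    g, s_out, s_in, _ = oriented_parameters(env)
    if s_out <= 0:
        raise ValidationError(
            "ratio_fixed_points requires a positive switching rate out of "
            "the majority phenotype (a in growth, b in stress)"
        )
    B = g - s_out + s_in
    disc = B * B + 4.0 * s_out * s_in
    sqrt_disc = math.sqrt(disc)
    if B >= 0:
        r_stable = (B + sqrt_disc) / (2.0 * s_out)
        r_unstable = -2.0 * s_in / (B + sqrt_disc) if (B + sqrt_disc) > 0 else 0.0
    else:
        r_unstable = (B - sqrt_disc) / (2.0 * s_out)
        r_stable = -2.0 * s_in / (B - sqrt_disc)
    return RatioFixedPoints(r_unstable=r_unstable, r_stable=r_stable)


def _gap_for(env: EnvironmentParams, gaps: RateGaps) -> float:
    """Pick and validate the gap matching the environment's condition."""
    _, _, _, majority_normal = oriented_parameters(env)
    return gaps.require_growth() if majority_normal else gaps.require_stress()


def steady_state_structure(env: EnvironmentParams, gaps: RateGaps) -> SteadyStateStructure:
    """Leading-order (small-switching) steady state of ``env``.

    Growth medium: ratio_star = delta_mu/a, persister_fraction =
    1/(1 + ratio_star), effective_rate = mu_n - a.  Stress: ratio_star =
    delta_kappa/b (p/n), effective_rate = -(kappa_p + b).  The relaxation
    rate is the exact linearization of the ratio equation at its stable
    fixed point, sqrt((g - s_out + s_in)^2 + 4 s_out s_in), i.e. the gap
    plus first-order switching corrections.
    """
    g, s_out, s_in, majority_normal = oriented_parameters(env)
    gap = _gap_for(env, gaps)
    if s_out <= 0:
        raise ValidationError("steady_state_structure requires s_out > 0")
    warn_if_not_small_switching(env.switching, gap, "steady_state_structure")
    ratio_star = gap / s_out
    persister_fraction = (
        1.0 / (1.0 + ratio_star) if majority_normal else ratio_star / (1.0 + ratio_star)
    )
    B = g - s_out + s_in
    relaxation = math.sqrt(B * B + 4.0 * s_out * s_in)
    if majority_normal:
        effective = env.rates.mu_n - env.switching.a
    else:
        effective = -(env.rates.kappa_p + env.switching.b)
    return SteadyStateStructure(
        ratio_star=ratio_star,
        persister_fraction=persister_fraction,
        relaxation_rate=relaxation,
        effective_rate=effective,
    )


def stationary_phase_fraction(sw: SwitchingRates) -> float:
    """Persister fraction in a non-growing (stationary-phase) population,
    ``a/(a+b)``: with growth shut off the structure is set purely by the
    balance of two-way switching."""
    if sw.a + sw.b <= 0:
        raise ValidationError(
            "stationary-phase fraction is undefined when both switching rates are zero"
        )
    return sw.a / (sw.a + sw.b)


def logistic_ratio(t: float, r0: float, env: EnvironmentParams, gaps: RateGaps) -> float:
    """Logistic-approximation oriented ratio at time ``t`` (hours after
    the moment the ratio was ``r0``).

    Solution of dr/dt = g r (1 - r/r*) with r* = g/s_out:

        r(t) = r* r0 / (r0 + (r* - r0) e^{-g t})

    Exact at t = 0; approaches r* as t grows.  ``r0`` must be the ratio
    in the orientation of ``env`` (n/p in growth, p/n in stress).
    """
    if r0 < 0:
        raise ValidationError(f"initial ratio must be nonnegative, got {r0}")
    g, s_out, _, _ = oriented_parameters(env)
    gap = _gap_for(env, gaps)
    if s_out <= 0:
        raise ValidationError("logistic_ratio requires s_out > 0")
    warn_if_not_small_switching(env.switching, gap, "logistic_ratio")
    r_star = g / s_out
    if r0 == 0.0:
        return 0.0
    # inverse-space form is overflow-safe for any g*t
    return r_star * r0 / (r0 + (r_star - r0) * math.exp(-g * t))


def _logistic_integrals(T: float, r0: float, r_star: float, g: float) -> tuple[float, float]:
    """(I_r, I_inv) = (int_0^T r dt, int_0^T dt/r) for the logistic ratio.

    I_r  = (r*/g) * ln(1 + (r0/r*) (e^{gT} - 1))
    I_inv = T/r* + (1/r0 - 1/r*) (1 - e^{-gT}) / g
    """
    x = r0 / r_star
    # log1p-form, overflow-safe: ln(x e^{gT} + 1 - x) = gT + ln(x + (1-x)e^{-gT})
    I_r = (r_star / g) * (g * T + math.log(x + (1.0 - x) * math.exp(-g * T)))
    inv_r0 = 0.0 if math.isinf(r0) else 1.0 / r0
    I_inv = T / r_star + (inv_r0 - 1.0 / r_star) * (1.0 - math.exp(-g * T)) / g
    return I_r, I_inv


def average_subpop_growth(
    t0: float, t: float, env: EnvironmentParams, gaps: RateGaps, r0: float
) -> tuple[float, float]:
    """Time-averaged effective per-capita rates of the normal and
    persister subpopulations over ``[t0, t]``, switching fluxes included.

    The instantaneous rates are ``mu_x - s_out + s_in / r`` for the
    majority and ``mu_y - s_in + s_out * r`` for the minority; averaging
    the logistic ratio gives closed forms.  Returns ``(rate_normal,
    rate_persister)`` regardless of orientation.  With no switching this
    reduces to ``(mu_n, mu_p)`` exactly.
    """
    if not t > t0:
        raise ValidationError("average_subpop_growth requires t > t0")
    g, s_out, s_in, majority_normal = oriented_parameters(env)
    T = t - t0
    mu_n, mu_p = env.rates.mu_n, env.rates.mu_p
    if s_out == 0.0 and s_in == 0.0:
        return mu_n, mu_p
    if s_out <= 0:
        raise ValidationError("average_subpop_growth requires s_out > 0")
    gap = _gap_for(env, gaps)
    warn_if_not_small_switching(env.switching, gap, "average_subpop_growth")
    r_star = g / s_out
    if r0 < 0:
        raise ValidationError(f"initial ratio must be nonnegative, got {r0}")
    I_r, I_inv = _logistic_integrals(T, r0, r_star, g)
    mu_major = mu_n if majority_normal else mu_p
    mu_minor = mu_p if majority_normal else mu_n
    rate_major = mu_major - s_out + s_in * I_inv / T
    rate_minor = mu_minor - s_in + s_out * I_r / T
    if majority_normal:
        return rate_major, rate_minor
    return rate_minor, rate_major


def total_double_exponential(
    t: float, n0: float, p0: float, env: EnvironmentParams, gaps: RateGaps
) -> float:
    """Double-exponential total population N(t) in the small-switching
    approximation.

    First-order eigenstructure of the rate matrix gives

        N(t) = (n0 + e) exp[(mu_n - a) t] + (p0 - e) exp[(mu_p - b) t]

    with mixing amplitude ``e = (a n0 + b p0) / d`` and spectral gap
    ``d = (mu_n - a) - (mu_p - b)``.  Exactly ``n0 + p0`` at t = 0.  In a
    growth medium the first term is the fast-growing component; under
    stress (d < 0) it is the fast-decaying one.
    """
    if n0 < 0 or p0 < 0:
        raise ValidationError("initial counts must be nonnegative")
    _gap_for(env, gaps)
    a, b = env.switching.a, env.switching.b
    lam_n = env.rates.mu_n - a
    lam_p = env.rates.mu_p - b
    d = lam_n - lam_p
    if d == 0.0:
        raise ValidationError(
            "double-exponential form degenerates when the two effective rates coincide"
        )
    warn_if_not_small_switching(env.switching, d, "total_double_exponential")
    e = (a * n0 + b * p0) / d
    return (n0 + e) * math.exp(lam_n * t) + (p0 - e) * math.exp(lam_p * t)


def average_total_growth(
    t: float, env: EnvironmentParams, gaps: RateGaps, r0: float
) -> float:
    """Time-averaged per-capita rate of the total population over
    ``[0, t]``, ``ln(N(t)/N(0)) / t``, in closed form.

    Tracks the majority subpopulation (whose averaged rate is available
    in closed form) and corrects by the change in the oriented ratio:
    ``ln N(t)/N(0) = ln x(t)/x(0) + ln[(1 + 1/r(t)) / (1 + 1/r0)]``
    with x the majority count.  ``r0`` may be ``inf`` (no minority cells
    initially).  With no switching the decoupled exact form is used.
    """
    if not t > 0:
        raise ValidationError("average_total_growth requires t > 0")
    g, s_out, s_in, majority_normal = oriented_parameters(env)
    mu_n, mu_p = env.rates.mu_n, env.rates.mu_p
    mu_major = mu_n if majority_normal else mu_p
    mu_minor = mu_p if majority_normal else mu_n
    if s_out == 0.0 and s_in == 0.0:
        inv_r0 = 0.0 if math.isinf(r0) else 1.0 / r0
        # N = x0 e^{mu_major t} + y0 e^{mu_minor t}, y0/x0 = 1/r0
        return (
            mu_major * t
            + math.log1p(inv_r0 * math.exp(-g * t))
            - math.log1p(inv_r0)
        ) / t
    if s_out <= 0:
        raise ValidationError("average_total_growth requires s_out > 0")
    gap = _gap_for(env, gaps)
    warn_if_not_small_switching(env.switching, gap, "average_total_growth")
    if r0 <= 0:
        raise ValidationError("initial oriented ratio must be positive (may be inf)")
    r_star = g / s_out
    _, I_inv = _logistic_integrals(t, r0, r_star, g)
    inv_r0 = 0.0 if math.isinf(r0) else 1.0 / r0
    inv_rt = 1.0 / r_star + (inv_r0 - 1.0 / r_star) * math.exp(-g * t)
    log_major = (mu_major - s_out) * t + s_in * I_inv
    return (log_major + math.log1p(inv_rt) - math.log1p(inv_r0)) / t
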