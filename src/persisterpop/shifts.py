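"""Observables of medium-shift experiments.

Shifting a culture from growth medium into antibiotic (or back) produces
the classic biphasic curves: a fast-decaying phase (normal cells dying)
followed by a slow-decaying phase (persisters), or a slow-regrowth phase
followed by fast regrowth.  The kink sits where the two subpopulations
are equal in size; its timing carries the switching rates.  This module
computes those characteristic times from the logistic approximation,
inverts them to estimate the switching rates, and fits measured count
tables with the double-exponential forms.

The oriented subpopulation ratio of the exact linear dynamics obeys a
Riccati equation, so the crossing times below are closed forms that are
*exact* for the model (no small-switching approximation), written with
the Riccati fixed points r_u < 0 < r_s and relaxation rate
lam = sqrt((g - s_out + s_in)^2 + 4 s_out s_in):

* transition time  T — the new-majority/old-majority oriented ratio
  reaches 1 (both subpopulations equal):
  T = ln[ (1 - r_u)(r_s - r0') / ((r_s - 1)(r0' - r_u)) ] / lam
  with r0' = 1/r0 the post-shift oriented ratio.  Small-switching limit:
  T ~= ln(r0) / g.
* equilibration time  T' — inflection of the declining subpopulation's
  time-dependent per-capita rate, where the oriented ratio passes the
  midpoint (r_s + r_u)/2:  T' = ln[(r_s - r0')/(r0' - r_u)] / lam >= T.

When each shift starts from the steady-state structure of the previous
environment, the leading-order forms are

    T_s = ln(rho/a) / dkappa,   T_g = ln(rho/b) / dmu,
    rho = dmu dkappa / (dmu + dkappa),

inverted by  a = rho exp(-dkappa T_s),  b = rho exp(-dmu T_g).  The
prefactor rho (rather than the bare gap) accounts for the cells that
switch phenotype *during* the fast phase after the shift and seed the
slow component; ``simple=True`` selects the bare-gap variants
a = dmu exp(-dkappa T_s), b = dkappa exp(-dmu T_g) instead.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .params import RateGaps, SwitchingRates, ValidationError

__all__ = [
    "TransitionTimes",
    "DoubleExpFit",
    "SwitchingInference",
    "FitConvergenceError",
    "transition_time_stress",
    "transition_time_growth",
    "equilibration_times",
    "steady_transition_times",
    "infer_switching_rates",
    "fit_double_exponential",
    "locate_transition",
    "switching_rates_from_curves",
]


class FitConvergenceError(RuntimeError):
    """Nonlinear fit failed; carries the initializer and solver status."""

    def __init__(self, message: str, x0: Sequence[float], status: int):
        super().__init__(f"{message} (initializer={list(x0)}, solver status={status})")
        self.x0 = list(x0)
        self.status = status


@dataclass(frozen=True)
class TransitionTimes:
    """The four characteristic times of a pair of shift experiments (h):
    ``T_s`` fast->slow kill transition, ``T_g`` slow->fast regrowth
    transition, and the later structure-equilibration times ``T_s_prime``
    and ``T_g_prime``."""

    T_s: float
    T_g: float
    T_s_prime: float
    T_g_prime: float


@dataclass(frozen=True)
class DoubleExpFit:
    """Double-exponential fit ``N(t) = amp_fast e^{rate_fast t} +
    amp_slow e^{rate_slow t}`` of a count curve on log10 counts.

    "fast"/"slow" refer to the magnitude of the decay rate under stress
    and to the growth rate in growth medium.  ``degenerate`` flags data
    that a single exponential already explains.
    """

    amp_fast: float
    amp_slow: float
    rate_fast: float
    rate_slow: float
    rss: float
    condition: str
    degenerate: bool = False


@dataclass(frozen=True)
class SwitchingInference:
    """Switching rates recovered from the two transition times."""

    a_hat: float
    b_hat: float
    inputs: tuple[float, float, float, float]  # (delta_mu, delta_kappa, T_s, T_g)


def _riccati_points(g: float, s_out: float, s_in: float) -> tuple[float, float, float]:
    """Fixed points (r_u, r_s) and relaxation rate of the oriented-ratio
    Riccati equation dr/dt = -s_out r^2 + (g - s_out + s_in) r + s_in."""
    B = g - s_out + s_in
    lam = math.sqrt(B * B + 4.0 * s_out * s_in)
    r_s = (B + lam) / (2.0 * s_out)
    r_u = -2.0 * s_in / (B + lam) if (B + lam) > 0 else 0.0
    return r_u, r_s, lam


def _transition_time(
    r0: float, g: float, s_out: float, s_in: float, approx: bool, what: str
) -> float:
    """Exact Riccati time for the post-shift oriented ratio (starting at
    1/r0) to reach 1, or the ln(r0)/g small-switching limit."""
    if r0 <= 1.0:
        warnings.warn(
            f"{what}: pre-shift majority ratio r0={r0:g} <= 1, the population "
            "is already past the transition; returning 0",
            UserWarning,
            stacklevel=3,
        )
        return 0.0
    if approx:
        return math.log(r0) / g
    if s_out <= 0:
        raise ValidationError(f"{what}: full form requires a positive post-shift "
                              "switching rate (use approx=True otherwise)")
    r_u, r_s, lam = _riccati_points(g, s_out, s_in)
    if r_s <= 1.0:
        raise ValidationError(
            f"{what}: stable ratio {r_s:g} <= 1 — switching too fast for a "
            "biphasic transition in this condition"
        )
    x0 = 1.0 / r0
    return math.log((1.0 - r_u) * (r_s - x0) / ((r_s - 1.0) * (x0 - r_u))) / lam


def transition_time_stress(
    r0: float, gaps: RateGaps, sw: SwitchingRates, approx: bool = False
) -> float:
    """Time after a growth->stress shift at which persisters catch up with
    normal cells (the kink of the killing curve), for pre-shift ratio
    ``r0 = n/p``.  The default is the exact ratio-equation crossing;
    ``approx=True`` uses the limit ``ln(r0)/delta_kappa``."""
    dk = gaps.require_stress()
    return _transition_time(r0, dk, sw.b, sw.a, approx, "transition_time_stress")


def transition_time_growth(
    r0: float, gaps: RateGaps, sw: SwitchingRates, approx: bool = False
) -> float:
    """Time after a stress->growth shift at which normal cells catch up
    with persisters (slow->fast regrowth), for pre-shift ratio
    ``r0 = p/n``.  ``approx=True`` uses the limit ``ln(r0)/delta_mu``."""
    dm = gaps.require_growth()
    return _transition_time(r0, dm, sw.a, sw.b, approx, "transition_time_growth")


def equilibration_times(
    gaps: RateGaps,
    sw: SwitchingRates,
    r0_s: float,
    r0_g: float | None = None,
) -> tuple[float, float]:
    """Structure-equilibration times ``(T_s_prime, T_g_prime)``.

    ``r0_s`` is the n/p ratio at the growth->stress shift and ``r0_g``
    the p/n ratio at the stress->growth shift (defaults to ``r0_s``).
    Each is the inflection point of the declining subpopulation's
    time-dependent per-capita rate, i.e. the time the post-shift
    oriented ratio passes the midpoint of its fixed points,
    ``ln[(r_s - 1/r0)/(1/r0 - r_u)]/lam``; always at or after the
    corresponding transition time (the structure equilibrates later
    than the total-population rate changes).
    """
    if r0_g is None:
        r0_g = r0_s
    gaps.require_growth(), gaps.require_stress()
    if sw.a <= 0 or sw.b <= 0:
        raise ValidationError("equilibration times require a > 0 and b > 0")
    out = []
    for name, r0, g, s_out, s_in in (
        ("r0_s", r0_s, gaps.delta_kappa, sw.b, sw.a),
        ("r0_g", r0_g, gaps.delta_mu, sw.a, sw.b),
    ):
        if r0 <= 0:
            raise ValidationError(f"{name} must be positive, got {r0:g}")
        r_u, r_s, lam = _riccati_points(g, s_out, s_in)
        x0 = 1.0 / r0
        if x0 >= r_s:
            raise ValidationError(f"{name}={r0:g} too small: ratio starts past r_s")
        out.append(math.log((r_s - x0) / (x0 - r_u)) / lam)
    return out[0], out[1]


def effective_gap_rate(gaps: RateGaps) -> float:
    """``rho = delta_mu delta_kappa / (delta_mu + delta_kappa)``: the
    prefactor of the steady-state transition-time relations.  It arises
    because the slow component after a shift is seeded both by the
    minority already present (set by the previous environment's gap) and
    by cells switching during the post-shift fast phase (set by the new
    one)."""
    dm, dk = gaps.require_growth(), gaps.require_stress()
    return dm * dk / (dm + dk)


def steady_transition_times(
    gaps: RateGaps, sw: SwitchingRates, simple: bool = False
) -> TransitionTimes:
    """All four characteristic times assuming each shift starts from the
    steady-state structure of the preceding environment
    (``r0 = delta_mu/a`` before stress, ``delta_kappa/b`` before growth):

        T_s = ln(rho/a) / delta_kappa,   T_g = ln(rho/b) / delta_mu

    with ``rho = delta_mu delta_kappa/(delta_mu + delta_kappa)``; the
    exact inverses of :func:`infer_switching_rates`.  ``simple=True``
    drops the switching-during-kill correction and uses the bare-gap
    prefactors (``T_s = ln(delta_mu/a)/delta_kappa`` etc.).
    """
    dm, dk = gaps.require_growth(), gaps.require_stress()
    if sw.a <= 0 or sw.b <= 0:
        raise ValidationError("steady transition times require a > 0 and b > 0")
    if simple:
        T_s = math.log(dm / sw.a) / dk
        T_g = math.log(dk / sw.b) / dm
    else:
        rho = effective_gap_rate(gaps)
        T_s = math.log(rho / sw.a) / dk
        T_g = math.log(rho / sw.b) / dm
    T_s_prime, T_g_prime = equilibration_times(gaps, sw, dm / sw.a, dk / sw.b)
    return TransitionTimes(T_s=T_s, T_g=T_g, T_s_prime=T_s_prime, T_g_prime=T_g_prime)


def infer_switching_rates(
    gaps: RateGaps, T_s: float, T_g: float, simple: bool = False
) -> SwitchingInference:
    """Invert the steady-state transition-time relations:

        a = rho exp(-delta_kappa T_s),   b = rho exp(-delta_mu T_g),

    ``rho = delta_mu delta_kappa/(delta_mu + delta_kappa)``.
    ``simple=True`` uses the bare-gap variants
    ``a = delta_mu exp(-delta_kappa T_s)``,
    ``b = delta_kappa exp(-delta_mu T_g)`` (whose ``T = 0`` boundary
    values are the gaps themselves)."""
    dm, dk = gaps.require_growth(), gaps.require_stress()
    if T_s < 0 or T_g < 0:
        raise ValidationError("transition times must be nonnegative")
    pre_a = dm if simple else effective_gap_rate(gaps)
    pre_b = dk if simple else effective_gap_rate(gaps)
    a_hat = pre_a * math.exp(-dk * T_s)
    b_hat = pre_b * math.exp(-dm * T_g)
    return SwitchingInference(a_hat=a_hat, b_hat=b_hat, inputs=(dm, dk, T_s, T_g))


# ---------------------------------------------------------------------------
# fitting of measured (or synthetic) count curves


def _as_arrays(curve) -> tuple[np.ndarray, np.ndarray]:
    """Accept a CountTable, a DataFrame with time_h/cfu_total, or a pair
    of arrays."""
    if hasattr(curve, "frame"):  # CountTable
        df = curve.frame
        return df["time_h"].to_numpy(float), df["cfu_total"].to_numpy(float)
    if hasattr(curve, "columns"):  # DataFrame
        return curve["time_h"].to_numpy(float), curve["cfu_total"].to_numpy(float)
    t, c = curve
    return np.asarray(t, float), np.asarray(c, float)


def _linear_logfit(t: np.ndarray, logc: np.ndarray) -> tuple[float, float]:
    """Slope (1/h, natural log) and intercept (log10) of a straight-line
    fit to log10 counts."""
    slope10, icept = np.polyfit(t, logc, 1)
    return slope10 * math.log(10.0), icept


def fit_double_exponential(curve, condition: str) -> DoubleExpFit:
    """Least-squares double-exponential fit of a count curve on log10
    counts.

    ``condition`` is ``"stress"`` (biphasic kill) or ``"growth"``
    (biphasic regrowth); it only affects which component is labeled
    "fast".  The initializer is deterministic: the early-dominant
    component from a straight-line fit to the first third of the log
    curve, the late-dominant one from the last third, amplitudes by
    back-projection of the intercepts.
    """
    if condition not in ("stress", "growth"):
        raise ValidationError(f"condition must be 'stress' or 'growth', got {condition!r}")
    t, counts = _as_arrays(curve)
    if t.size < 6:
        raise ValidationError(f"need at least 6 time points, got {t.size}")
    if np.any(counts <= 0):
        raise ValidationError("all counts must be positive for a log-scale fit")
    t0 = t[0]
    tt = t - t0
    logc = np.log10(counts)

    third = max(t.size // 3, 2)
    lam_early, icept_early = _linear_logfit(tt[:third], logc[:third])
    lam_late, icept_late = _linear_logfit(tt[-third:], logc[-third:])

    scale = max(abs(lam_early), abs(lam_late), 1e-12)
    if abs(lam_early - lam_late) < 1e-6 * scale:
        # single-exponential data: one component carries everything
        lam, icept = _linear_logfit(tt, logc)
        amp = 10.0**icept
        return DoubleExpFit(
            amp_fast=amp,
            amp_slow=amp * 1e-12,
            rate_fast=lam,
            rate_slow=lam / 2.0,
            rss=float(np.sum((icept + lam / math.log(10.0) * tt - logc) ** 2)),
            condition=condition,
            degenerate=True,
        )

    # params: log10 amplitudes (positivity) and rates of the two components
    x0 = np.array([icept_early, lam_early, icept_late, lam_late])

    def model_log10(x, tt):
        la1, l1, la2, l2 = x
        # log10 of A1 e^{l1 t} + A2 e^{l2 t}, computed stably
        u1 = la1 + l1 * tt / math.log(10.0)
        u2 = la2 + l2 * tt / math.log(10.0)
        hi = np.maximum(u1, u2)
        return hi + np.log10(10.0 ** (u1 - hi) + 10.0 ** (u2 - hi))

    def resid(x):
        return model_log10(x, tt) - logc

    sol = least_squares(resid, x0, method="lm", xtol=1e-14, ftol=1e-14, max_nfev=5000)
    if not sol.success:
        raise FitConvergenceError("double-exponential fit did not converge", x0, sol.status)
    la1, l1, la2, l2 = sol.x
    comps = [(10.0**la1, l1), (10.0**la2, l2)]
    rss = float(np.sum(sol.fun**2))

    if abs(l1 - l2) < 1e-8 * max(abs(l1), abs(l2), 1e-12):
        amp = comps[0][0] + comps[1][0]
        lam = 0.5 * (l1 + l2)
        return DoubleExpFit(amp, amp * 1e-12, lam, lam / 2.0, rss, condition, degenerate=True)

    # "fast" = larger decay-rate magnitude under stress, larger growth rate in growth
    if condition == "stress":
        fast, slow = sorted(comps, key=lambda c: c[1])  # more negative rate first
    else:
        fast, slow = sorted(comps, key=lambda c: -c[1])  # larger rate first
    degenerate = bool(slow[0] < 1e-9 * fast[0])
    # report amplitudes at the curve's own t0 (tt = 0)
    return DoubleExpFit(
        amp_fast=float(fast[0]),
        amp_slow=float(slow[0]),
        rate_fast=float(fast[1]),
        rate_slow=float(slow[1]),
        rss=rss,
        condition=condition,
        degenerate=degenerate,
    )


def locate_transition(fit: DoubleExpFit) -> float:
    """Time (hours after the fitted curve's first sample) at which the two
    fitted components are equal in size — the data-side estimate of the
    transition time.

    Stress: the fast-decaying component starts above and crosses the slow
    one at ``t* = ln(amp_fast/amp_slow)/(|rate_fast| - |rate_slow|)``.
    Growth: the slow component starts above, ``t* = ln(amp_slow/amp_fast)
    / (rate_fast - rate_slow)``.
    """
    if fit.rate_fast == fit.rate_slow:
        raise ValidationError("cannot locate a transition with equal component rates")
    if fit.condition == "stress":
        return math.log(fit.amp_fast / fit.amp_slow) / (
            abs(fit.rate_fast) - abs(fit.rate_slow)
        )
    return math.log(fit.amp_slow / fit.amp_fast) / (fit.rate_fast - fit.rate_slow)


def switching_rates_from_curves(
    stress_curve,
    growth_curve,
    gaps: RateGaps,
    ratio_star_growth: float | None = None,
) -> SwitchingInference:
    """Full data pipeline: fit both shift curves, locate the two
    transitions, and invert for the switching rates.

    ``stress_curve``/``growth_curve`` hold the post-shift segments
    (times relative to, or starting at, the shift).  If
    ``ratio_star_growth`` is given, warn when the fitted pre-shift
    structure differs from it by more than 2x (the inversion assumes the
    shift happened from steady state).
    """
    fit_s = fit_double_exponential(stress_curve, "stress")
    fit_g = fit_double_exponential(growth_curve, "growth")
    T_s = locate_transition(fit_s)
    T_g = locate_transition(fit_g)
    if ratio_star_growth is not None and fit_s.amp_slow > 0:
        fitted_ratio = fit_s.amp_fast / fit_s.amp_slow
        if not (0.5 < fitted_ratio / ratio_star_growth < 2.0):
            warnings.warn(
                f"pre-shift subpopulation ratio from the kill-curve fit "
                f"({fitted_ratio:.3g}) differs more than 2x from the expected "
                f"steady state ({ratio_star_growth:.3g}); the shift may have "
                "occurred before the structure equilibrated",
                UserWarning,
                stacklevel=2,
            )
    return infer_switching_rates(gaps, T_s, T_g)
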