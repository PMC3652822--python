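"""Parameter containers for the two-phenotype (normal/persister) model.

A bacterial population is split into normal cells ``n`` and persister
cells ``p``.  Each phenotype has a signed net per-capita rate in a given
environment (positive = growth, negative = death), and cells convert
stochastically between phenotypes with rates ``a`` (normal -> persister)
and ``b`` (persister -> normal).  All rates are per hour; time is in
hours throughout the package.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace


class ValidationError(ValueError):
    """Raised when model parameters or inputs violate their invariants."""


class SmallSwitchingWarning(UserWarning):
    """Emitted when an asymptotic formula is evaluated outside the
    small-switching-rate regime it was derived for."""


def _require_finite(name: str, value: float) -> float:
    value = float(value)
    if not math.isfinite(value):
        raise ValidationError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class PhenotypeRates:
    """Net per-capita rates of the two phenotypes (1/h).

    ``mu_n`` is the rate of normal cells, ``mu_p`` of persisters.  Under
    unstressed growth typically ``mu_n > mu_p >= 0``; under stress both
    are negative and the corresponding death rates are exposed as
    ``kappa_n = -mu_n`` and ``kappa_p = -mu_p``.
    """

    mu_n: float
    mu_p: float

    def __post_init__(self) -> None:
        _require_finite("mu_n", self.mu_n)
        _require_finite("mu_p", self.mu_p)

    @property
    def kappa_n(self) -> float:
        """Death rate of normal cells, ``-mu_n`` (1/h)."""
        return -self.mu_n

    @property
    def kappa_p(self) -> float:
        """Death rate of persisters, ``-mu_p`` (1/h)."""
        return -self.mu_p

    @property
    def delta_mu(self) -> float:
        """Growth-rate gap ``mu_n - mu_p`` (positive in a growth medium)."""
        return self.mu_n - self.mu_p

    @property
    def delta_kappa(self) -> float:
        """Death-rate gap ``kappa_n - kappa_p`` (positive under stress)."""
        return self.kappa_n - self.kappa_p


@dataclass(frozen=True)
class SwitchingRates:
    """Stochastic phenotype-switching rates (1/h).

    ``a``: normal -> persister; ``b``: persister -> normal.  Both are
    nonnegative and, in the organisms this model describes, small
    compared to the growth/death rates (1e-6 .. 1e-1 per hour).
    """

    a: float
    b: float

    def __post_init__(self) -> None:
        _require_finite("a", self.a)
        _require_finite("b", self.b)
        if self.a < 0 or self.b < 0:
            raise ValidationError(
                f"switching rates must be nonnegative, got a={self.a}, b={self.b}"
            )


@dataclass(frozen=True)
class EnvironmentParams:
    """One environmental condition: phenotype rates, switching rates and
    an optional carrying capacity (``math.inf`` = unbounded growth)."""

    rates: PhenotypeRates
    switching: SwitchingRates
    label: str = ""
    carrying_capacity: float = math.inf

    def __post_init__(self) -> None:
        if not self.carrying_capacity > 0:
            raise ValidationError(
                f"carrying_capacity must be positive, got {self.carrying_capacity}"
            )

    @property
    def has_capacity(self) -> bool:
        return math.isfinite(self.carrying_capacity)

    def without_capacity(self) -> "EnvironmentParams":
        return replace(self, carrying_capacity=math.inf)


def growth_environment(
    mu_n: float,
    mu_p: float,
    a: float,
    b: float,
    carrying_capacity: float = math.inf,
    label: str = "growth",
) -> EnvironmentParams:
    """Convenience constructor for an unstressed growth medium (mu_n > mu_p)."""
    return EnvironmentParams(
        rates=PhenotypeRates(mu_n, mu_p),
        switching=SwitchingRates(a, b),
        label=label,
        carrying_capacity=carrying_capacity,
    )


def stress_environment(
    kappa_n: float,
    kappa_p: float,
    a: float,
    b: float,
    label: str = "stress",
) -> EnvironmentParams:
    """Convenience constructor for a stress medium given death rates
    (kappa = -mu, kappa_n > kappa_p)."""
    return EnvironmentParams(
        rates=PhenotypeRates(-kappa_n, -kappa_p),
        switching=SwitchingRates(a, b),
        label=label,
    )


@dataclass(frozen=True)
class RateGaps:
    """The two rate differences that control every asymptotic formula:
    ``delta_mu = mu_n - mu_p`` in the growth medium and
    ``delta_kappa = kappa_n - kappa_p`` under stress (both 1/h)."""

    delta_mu: float
    delta_kappa: float

    def __post_init__(self) -> None:
        _require_finite("delta_mu", self.delta_mu)
        _require_finite("delta_kappa", self.delta_kappa)

    def require_growth(self) -> float:
        if not self.delta_mu > 0:
            raise ValidationError(
                f"delta_mu must be positive for a growth condition, got {self.delta_mu}"
            )
        return self.delta_mu

    def require_stress(self) -> float:
        if not self.delta_kappa > 0:
            raise ValidationError(
                f"delta_kappa must be positive for a stress condition, got {self.delta_kappa}"
            )
        return self.delta_kappa


# fraction of the relevant gap above which the small-switching formulas are
# considered out of their validity regime (warning only, not an error)
SMALL_SWITCHING_FRACTION = 0.1


def warn_if_not_small_switching(
    sw: SwitchingRates, gap: float, context: str, fraction: float = SMALL_SWITCHING_FRACTION
) -> None:
    if max(sw.a, sw.b) > fraction * abs(gap):
        warnings.warn(
            f"{context}: switching rates (a={sw.a:g}, b={sw.b:g}) exceed "
            f"{fraction:.0%} of the rate gap {gap:g}/h; the small-switching "
            "approximation may be inaccurate",
            SmallSwitchingWarning,
            stacklevel=3,
        )
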