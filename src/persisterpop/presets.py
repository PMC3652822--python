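"""Canonical parameter sets used in examples and tests.

Magnitudes follow the persistence literature for *E. coli* type-II-like
persisters: normal cells grow at ~2/h and persisters at ~0.2/h in rich
medium; under bactericidal antibiotic the normal cells die at ~2/h while
persisters die an order of magnitude more slowly; switching rates are
tiny, 1e-6..1e-1 per hour.
"""

from __future__ import annotations

from .params import EnvironmentParams, RateGaps, growth_environment, stress_environment

__all__ = ["ecoli_growth", "ecoli_stress", "ecoli_gaps"]

#: default switching rates (1/h): rare entry into persistence, faster exit
DEFAULT_A = 1e-5
DEFAULT_B = 1e-3

MU_N_GROWTH = 2.0
MU_P_GROWTH = 0.2
KAPPA_N_STRESS = 2.0
KAPPA_P_STRESS = 0.1


def ecoli_growth(a: float = DEFAULT_A, b: float = DEFAULT_B, **kw) -> EnvironmentParams:
    """Rich growth medium: mu_n = 2/h, mu_p = 0.2/h."""
    return growth_environment(MU_N_GROWTH, MU_P_GROWTH, a, b, **kw)


def ecoli_stress(a: float = DEFAULT_A, b: float = DEFAULT_B) -> EnvironmentParams:
    """Bactericidal antibiotic: kappa_n = 2/h, kappa_p = 0.1/h."""
    return stress_environment(KAPPA_N_STRESS, KAPPA_P_STRESS, a, b)


def ecoli_gaps() -> RateGaps:
    return RateGaps(
        delta_mu=MU_N_GROWTH - MU_P_GROWTH,
        delta_kappa=KAPPA_N_STRESS - KAPPA_P_STRESS,
    )
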