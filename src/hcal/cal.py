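"""Cross-sectional average length of life (CAL).

CAL(t) summarizes, for one reference year t, the actual mortality
history of every cohort alive at t: it integrates over age the
proportion p_c(x, t-x) of the cohort born in year t-x that survived
from birth to exact age x.  Unlike a life-table survivorship, the
cross-sectional function x -> p_c(x) need not be monotone: a cohort hit
by harsher conditions than its elders (e.g. a birth cohort born into
wartime) leaves a visible upward step at its current age.

Survivorship is reconstructed by chaining *period* death rates along
Lexis diagonals: the cohort reaching exact age x at time t is labelled
t-x and its one-year death probabilities are read from cells
(a, t-x+a), a = 0..x-1.  Each year of age is therefore attributed
wholly to one calendar year, which is the standard reconstruction when
true cohort triangle rates are unavailable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError, MissingDataError
from .lifetable import MortalitySurface, mx_to_qx, separation_factors

__all__ = ["CohortSurvivorship", "reconstruct_cohort_survivorship", "cal"]


@dataclass(frozen=True)
class CohortSurvivorship:
    """The diagonal survivorship p_c(x, t-x) for one reference year.

    Attributes
    ----------
    reference_year
        The year t at which all cohorts are observed.
    ages
        0..max_age (max_age = omega, or the truncation age).
    p_c
        p_c[x] = probability that the cohort born in t-x survived to
        exact age x; p_c[0] = 1 by the radix convention.  Not
        necessarily monotone in x.
    L_c
        Person-years lived in [x, x+1) per initial newborn, built from
        p_c with the same separation factors as a life table.
    birth_cohorts
        birth_cohorts[x] = t - x.
    truncated
        True when the series stops before the configured terminal age.
    """

    reference_year: int
    ages: np.ndarray
    p_c: np.ndarray
    L_c: np.ndarray
    birth_cohorts: np.ndarray
    truncated: bool = False
    sex_label: str = ""

    def __post_init__(self):
        p = np.asarray(self.p_c, dtype=float)
        if p[0] != 1.0:
            raise InvalidArgumentError("p_c(0) must be 1 (radix convention)")
        if np.any(p < 0) or np.any(p > 1):
            raise InvalidArgumentError("p_c values must lie in [0, 1]")
        if len(self.ages) != len(p) or len(self.L_c) != len(p):
            raise InvalidArgumentError("ages, p_c and L_c must share one grid")

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])


def reconstruct_cohort_survivorship(
    surface: MortalitySurface,
    reference_year: int,
    omega: int | None = None,
    a0_rule: str = "keyfitz",
    close_with_exposure: bool = True,
    allow_truncated_to: int | None = None,
) -> CohortSurvivorship:
    """Chain period death rates along Lexis diagonals up to reference_year.

    Requires the surface to cover years reference_year - omega ..
    reference_year; computing CAL for year t with terminal age 100
    therefore needs data back to t-100.  ``allow_truncated_to`` computes
    an explicitly truncated series over 0..AGE instead of raising when
    the history is too short.
    """
    t = int(reference_year)
    if omega is None:
        omega = surface.omega
    if omega > surface.omega:
        raise InvalidArgumentError(
            f"omega={omega} exceeds the surface's terminal age {surface.omega}"
        )
    max_age = omega
    truncated = False
    if allow_truncated_to is not None:
        if not (1 <= allow_truncated_to <= omega):
            raise InvalidArgumentError(
                f"truncation age must lie in 1..{omega}, got {allow_truncated_to}"
            )
        max_age = int(allow_truncated_to)
        truncated = max_age < omega
    first_needed = t - max_age
    if t > surface.years[-1] or first_needed < surface.years[0]:
        raise MissingDataError(
            f"CAL({t}) with terminal age {max_age} requires years "
            f"{first_needed}..{t}; surface covers "
            f"{surface.years[0]}..{surface.years[-1]}"
        )

    # One-year death probabilities per cell, with cohort-specific a(0):
    # the infant conversion for the cohort born in year y uses m(0, y).
    rates = surface.rates
    y0 = int(surface.years[0])

    def q_cell(age: int, year: int) -> float:
        m = rates[age, year - y0]
        if np.isnan(m):
            raise MissingDataError(
                f"missing death rate at (age {age}, year {year}) needed for CAL({t})"
            )
        if age == 0:
            a = separation_factors(np.array([m]), a0_rule)[0]
        else:
            a = 0.5
        return mx_to_qx(m, 1.0, a)

    ages = np.arange(max_age + 1)
    p_c = np.empty(max_age + 1)
    p_c[0] = 1.0
    for x in range(1, max_age + 1):
        # cohort born t-x traverses cells (a, t-x+a), a = 0..x-1
        p = 1.0
        birth = t - x
        for a in range(x):
            p *= 1.0 - q_cell(a, birth + a)
        p_c[x] = p

    # Person-years per age interval with life-table separation factors;
    # the infant factor uses m(0, t) so a stationary surface reproduces
    # the period table bit-for-bit.
    m_infant = rates[0, t - y0]
    if np.isnan(m_infant):
        raise MissingDataError(
            f"missing death rate at (age 0, year {t}) needed for CAL({t})"
        )
    ax = separation_factors(np.array([m_infant] + [0.0] * max_age), a0_rule)
    L_c = np.empty(max_age + 1)
    L_c[:-1] = p_c[1:] + ax[:-1] * (p_c[:-1] - p_c[1:])
    m_term = rates[max_age, t - y0]
    if np.isnan(m_term):
        raise MissingDataError(
            f"missing death rate at (age {max_age}, year {t}) needed for CAL({t})"
        )
    if close_with_exposure and m_term > 0:
        with np.errstate(over="ignore"):
            L_term = p_c[-1] / m_term
        L_c[-1] = L_term if np.isfinite(L_term) else 0.0
    else:
        L_c[-1] = 0.0

    return CohortSurvivorship(
        reference_year=t,
        ages=ages,
        p_c=p_c,
        L_c=L_c,
        birth_cohorts=t - ages,
        truncated=truncated,
        sex_label=surface.sex_label,
    )


def cal(cs: CohortSurvivorship) -> float:
    """CAL(t) = sum over ages of the diagonal person-years L_c(x).

    The cohort radix is 1, so this is directly in years.  Summation
    runs from the oldest age down, matching the life-table T(x)
    accumulation so that a time-constant surface yields CAL(t) equal to
    the period life expectancy bit-for-bit.
    """
    return float(np.cumsum(cs.L_c[::-1])[-1])
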