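"""Synthetic mortality surfaces, prevalence curves and survey samples.

The generator plays the role of the national mortality database and the
health survey: a deterministic Gompertz-Makeham mortality surface with
a constant annual improvement factor (so the surface's only dynamics
are a secular decline in rates, optionally broken by a cohort shock on
chosen Lexis diagonals), a smooth logistic limitation-prevalence curve
rising with age, and finite survey samples drawn from that curve with
binomial noise and optional lognormal sampling weights.

Mortality is noise-free by design — observed death rates are treated as
fixed quantities — so all sampling variability lives in the survey, and
every downstream measure has an exact generator ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .lifetable import MortalitySurface
from .prevalence import SurveySample

__all__ = [
    "CohortShock",
    "SyntheticScenario",
    "make_surface",
    "make_prevalence",
    "draw_survey",
    "france_like",
]


@dataclass(frozen=True)
class CohortShock:
    """Excess mortality on one birth cohort's Lexis diagonal.

    The death rates in cells (x, birth_year + x) for age_lo <= x <=
    age_hi are multiplied by ``multiplier``.
    """

    birth_year: int
    age_lo: int
    age_hi: int
    multiplier: float

    def __post_init__(self):
        if self.multiplier < 0:
            raise InvalidArgumentError("shock multiplier must be >= 0")
        if self.age_hi < self.age_lo or self.age_lo < 0:
            raise InvalidArgumentError("shock age range must satisfy 0 <= lo <= hi")


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of one synthetic study population.

    Mortality: rate(x, t) = (makeham_c + gompertz_a * exp(gompertz_b * x))
    * rho^(t - t0) with t0 the first generated year; rho = 1 freezes the
    surface in time.  Prevalence: a logistic in age between ``pi_floor``
    and ``pi_ceiling`` with midpoint ``pi_midpoint`` and slope
    ``pi_steepness``.  Surveys: ``n_per_age`` respondents per single
    age, weights lognormal with sigma ``weight_sigma`` (0 = unit
    weights).
    """

    gompertz_a: float = 3e-5
    gompertz_b: float = 0.105
    makeham_c: float = 3e-4
    rho: float = 0.98
    shock: CohortShock | None = None
    pi_floor: float = 0.03
    pi_ceiling: float = 0.75
    pi_midpoint: float = 62.0
    pi_steepness: float = 0.085
    n_per_age: int = 500
    weight_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.gompertz_a <= 0 or self.gompertz_b <= 0 or self.makeham_c < 0:
            raise InvalidArgumentError("need gompertz a > 0, b > 0, makeham c >= 0")
        if not (0 < self.rho <= 1):
            raise InvalidArgumentError("improvement factor rho must lie in (0, 1]")
        if not (0 <= self.pi_floor <= self.pi_ceiling <= 1):
            raise InvalidArgumentError("need 0 <= pi_floor <= pi_ceiling <= 1")


def make_surface(scenario: SyntheticScenario, years, omega: int = 100) -> MortalitySurface:
    """Deterministic mortality surface for the scenario.

    rate(x, t) = (c + a e^{bx}) rho^{t - t0}, with the cohort-shock
    multiplier applied afterwards on the shocked diagonal cells.
    """
    years = np.asarray(years, dtype=int)
    if not np.array_equal(years, np.arange(years[0], years[-1] + 1)):
        raise InvalidArgumentError("years must be contiguous")
    ages = np.arange(omega + 1)
    base = scenario.makeham_c + scenario.gompertz_a * np.exp(scenario.gompertz_b * ages)
    factor = scenario.rho ** (years - years[0]).astype(float)
    rates = np.outer(base, factor)
    if scenario.shock is not None:
        s = scenario.shock
        for x in range(s.age_lo, s.age_hi + 1):
            yr = s.birth_year + x
            if years[0] <= yr <= years[-1] and x <= omega:
                rates[x, yr - years[0]] *= s.multiplier
    return MortalitySurface(
        ages=ages,
        years=years,
        rates=rates,
        sex_label="synthetic",
        source_label="hcal.synthetic",
    )


def make_prevalence(scenario: SyntheticScenario, ages) -> np.ndarray:
    """True limitation-prevalence curve pi(x) on the given ages."""
    ages = np.asarray(ages, dtype=float)
    lo, hi = scenario.pi_floor, scenario.pi_ceiling
    return lo + (hi - lo) / (
        1.0 + np.exp(-scenario.pi_steepness * (ages - scenario.pi_midpoint))
    )


def draw_survey(
    true_pi,
    ages,
    n_per_age: int,
    year: int,
    weight_sigma: float = 0.0,
    seed=None,
    population: str = "synthetic",
) -> SurveySample:
    """Finite survey: n_per_age Bernoulli(pi(x)) respondents per age.

    Weights are lognormal(0, weight_sigma), or all 1 when sigma = 0;
    the draw is reproducible under a fixed seed (an int or an existing
    Generator).
    """
    ages = np.asarray(ages, dtype=int)
    pi = np.asarray(true_pi, dtype=float)
    if len(pi) != len(ages):
        raise InvalidArgumentError("true_pi and ages must share one grid")
    if np.any(pi < 0) or np.any(pi > 1):
        raise InvalidArgumentError("true prevalence must lie in [0, 1]")
    if n_per_age < 1:
        raise InvalidArgumentError("n_per_age must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_total = len(ages) * n_per_age
    age_col = np.repeat(ages, n_per_age)
    unhealthy = rng.random(n_total) < np.repeat(pi, n_per_age)
    if weight_sigma > 0:
        weights = rng.lognormal(mean=0.0, sigma=weight_sigma, size=n_total)
    else:
        weights = np.ones(n_total)
    df = pd.DataFrame(
        {"age": age_col, "unhealthy": unhealthy.astype(int), "weight": weights}
    )
    return SurveySample(data=df, year=year, population=population)


def france_like(**overrides) -> SyntheticScenario:
    """A packaged scenario with a plausible Western-European scale.

    Parameters were calibrated once so that, on a 1905-2015 surface
    with terminal age 100 and annual improvement rho = 0.98, the
    final-year period life expectancy is about 79 years and CAL about
    74 years.  These are generator truths for documentation and tests,
    not estimates of any real population.
    """
    base = SyntheticScenario(
        gompertz_a=9.762e-05,
        gompertz_b=0.105,
        makeham_c=0.010,
        rho=0.98,
        pi_floor=0.03,
        pi_ceiling=0.75,
        pi_midpoint=62.0,
        pi_steepness=0.085,
        n_per_age=500,
        weight_sigma=0.25,
    )
    return replace(base, **overrides) if overrides else base
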