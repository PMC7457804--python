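"""Sullivan apportionment of person-years into healthy life years.

Two variants share one prevalence schedule pi(x, t):

* HE  = (1/l0) * sum_x (1 - pi(x)) * L(x)   — period person-years
  from a conventional period life table (health expectancy);
* HCAL = sum_x (1 - pi(x)) * L_c(x)          — diagonal-cohort
  person-years from the cross-sectional cohort survivorship, giving
  the cross-sectional average length of healthy life.

The two measures differ only in the survivorship behind the
person-years; combining cohort survivors with the health of the same
real cohorts makes HCAL the conceptually coherent pairing, while HE
pairs real-cohort health with a hypothetical period cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cal import CohortSurvivorship, cal, reconstruct_cohort_survivorship
from .errors import InvalidArgumentError
from .lifetable import LifeTable, MortalitySurface, build_period_lifetable
from .prevalence import PrevalenceSchedule
from .uncertainty import IntervalEstimate, schedule_variances, sullivan_variance

__all__ = [
    "HealthSummary",
    "healthy_survival_curve",
    "sullivan_he",
    "sullivan_hcal",
    "summarize",
    "compare",
]


def _prevalence_pi(prevalence, ages=None):
    """Extract (ages, pi) from a PrevalenceSchedule or a plain array."""
    if isinstance(prevalence, PrevalenceSchedule):
        return prevalence.ages, prevalence.pi
    pi = np.asarray(prevalence, dtype=float)
    return ages, pi


def _check_pi(pi):
    if np.any(np.isnan(pi)) or np.any(pi < 0) or np.any(pi > 1):
        raise InvalidArgumentError("prevalence values must lie in [0, 1] with no gaps")


def _align(grid_a, grid_b, what_a, what_b):
    if grid_a is not None and grid_b is not None and not np.array_equal(grid_a, grid_b):
        raise InvalidArgumentError(
            f"age grid mismatch: {what_a} covers {grid_a[0]}..{grid_a[-1]} "
            f"({len(grid_a)} ages), {what_b} covers {grid_b[0]}..{grid_b[-1]} "
            f"({len(grid_b)} ages)"
        )


def healthy_survival_curve(survivorship, prevalence) -> np.ndarray:
    """Probability of being alive *and* healthy at each age.

    curve(x) = survivorship(x) * (1 - pi(x)).  ``survivorship`` may be
    a CohortSurvivorship, a LifeTable (uses l(x)/l0), or a plain array
    of survival probabilities; ``prevalence`` a PrevalenceSchedule or a
    plain array on the same age grid.
    """
    if isinstance(survivorship, CohortSurvivorship):
        s_ages, s = survivorship.ages, survivorship.p_c
        s_name = "survivorship"
    elif isinstance(survivorship, LifeTable):
        s_ages, s = survivorship.ages, survivorship.survivorship()
        s_name = "survivorship"
    else:
        s = np.asarray(survivorship, dtype=float)
        s_ages, s_name = None, "survivorship"
    p_ages, pi = _prevalence_pi(prevalence)
    _align(s_ages, p_ages, s_name, "prevalence")
    if len(s) != len(pi):
        raise InvalidArgumentError(
            f"age grid mismatch: survivorship has {len(s)} ages, "
            f"prevalence has {len(pi)}"
        )
    _check_pi(pi)
    if np.any(s < 0) or np.any(s > 1):
        raise InvalidArgumentError("survivorship values must lie in [0, 1]")
    return s * (1.0 - pi)


def _weighted_years(person_years, radix, prevalence, ages, what):
    p_ages, pi = _prevalence_pi(prevalence)
    _align(ages, p_ages, what, "prevalence")
    if len(pi) != len(person_years):
        raise InvalidArgumentError(
            f"age grid mismatch: {what} has {len(person_years)} ages, "
            f"prevalence has {len(pi)}"
        )
    _check_pi(pi)
    # summed oldest-age-first, matching the life-table T(x) accumulation,
    # so stationary identities (HE = HCAL, and HE = LE when pi = 0) hold
    # bit-for-bit
    healthy = (1.0 - pi) * person_years
    return float(np.cumsum(healthy[::-1])[-1] / radix)


def sullivan_he(lt: LifeTable, prevalence) -> float:
    """Health expectancy: healthy person-years of a period life table."""
    return _weighted_years(lt.Lx, lt.radix, prevalence, lt.ages, "life table")


def sullivan_hcal(cs: CohortSurvivorship, prevalence) -> float:
    """Cross-sectional average length of healthy life."""
    return _weighted_years(cs.L_c, 1.0, prevalence, cs.ages, "cohort survivorship")


@dataclass(frozen=True)
class HealthSummary:
    """LE, HE, CAL and HCAL (years) for one population-year-sex.

    Ratio fields are computed properties, so they always equal the
    corresponding quotient.  SEs are optional (None when prevalence
    sample sizes were unavailable).
    """

    population: str
    year: int
    sex: str
    le: float
    he: float
    cal: float
    hcal: float
    he_se: float | None = None
    hcal_se: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.he <= self.le + 1e-12):
            raise InvalidArgumentError(f"need 0 <= HE <= LE, got HE={self.he}, LE={self.le}")
        if not (0.0 <= self.hcal <= self.cal + 1e-12):
            raise InvalidArgumentError(
                f"need 0 <= HCAL <= CAL, got HCAL={self.hcal}, CAL={self.cal}"
            )

    @property
    def ratio_he_le(self) -> float:
        return self.he / self.le

    @property
    def ratio_hcal_cal(self) -> float:
        return self.hcal / self.cal

    @property
    def he_interval(self) -> IntervalEstimate | None:
        if self.he_se is None:
            return None
        return IntervalEstimate(self.he, self.he_se)

    @property
    def hcal_interval(self) -> IntervalEstimate | None:
        if self.hcal_se is None:
            return None
        return IntervalEstimate(self.hcal, self.hcal_se)

    def to_dict(self) -> dict:
        d = {
            "population": self.population,
            "year": self.year,
            "sex": self.sex,
            "le": self.le,
            "he": self.he,
            "cal": self.cal,
            "hcal": self.hcal,
            "ratio_he_le": self.ratio_he_le,
            "ratio_hcal_cal": self.ratio_hcal_cal,
        }
        for name, iv in (("he", self.he_interval), ("hcal", self.hcal_interval)):
            if iv is not None:
                d[f"{name}_se"] = iv.se
                d[f"{name}_lo95"] = iv.lower95
                d[f"{name}_hi95"] = iv.upper95
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "HealthSummary":
        return cls(
            population=d.get("population", ""),
            year=int(d["year"]),
            sex=d.get("sex", ""),
            le=float(d["le"]),
            he=float(d["he"]),
            cal=float(d["cal"]),
            hcal=float(d["hcal"]),
            he_se=float(d["he_se"]) if d.get("he_se") is not None else None,
            hcal_se=float(d["hcal_se"]) if d.get("hcal_se") is not None else None,
        )


def summarize(
    surface: MortalitySurface,
    prevalence: PrevalenceSchedule,
    year: int,
    population: str = "",
    sex: str | None = None,
    omega: int | None = None,
    radix: float = 1.0,
    a0_rule: str = "keyfitz",
    close_with_exposure: bool = True,
    extend_below: str = "constant",
    with_se: bool = True,
) -> HealthSummary:
    """One-call pipeline: life table + CAL + Sullivan weighting + SEs.

    The prevalence schedule is extended to the full 0..omega grid
    (holding the youngest observed value downward by default, the
    oldest upward) before the Sullivan sums; SEs use the observed
    per-age sample sizes with the schedule's (smoothed) proportions.
    """
    if omega is None:
        omega = surface.omega
    lt = build_period_lifetable(
        surface, year, radix=radix, a0_rule=a0_rule,
        close_with_exposure=close_with_exposure,
    )
    lt = _truncate_lifetable(lt, omega)
    cs = reconstruct_cohort_survivorship(
        surface, year, omega=omega, a0_rule=a0_rule,
        close_with_exposure=close_with_exposure,
    )
    sched = prevalence.extend_to(np.arange(omega + 1), below=extend_below)
    he = sullivan_he(lt, sched)
    hcal_v = sullivan_hcal(cs, sched)
    he_se = hcal_se = None
    if with_se and np.any(sched.n > 0):
        var_pi = schedule_variances(sched)
        he_se = float(np.sqrt(sullivan_variance(lt.Lx, lt.radix, var_pi)))
        hcal_se = float(np.sqrt(sullivan_variance(cs.L_c, 1.0, var_pi)))
    return HealthSummary(
        population=population,
        year=year,
        sex=surface.sex_label if sex is None else sex,
        le=lt.e0,
        he=he,
        cal=cal(cs),
        hcal=hcal_v,
        he_se=he_se,
        hcal_se=hcal_se,
    )


def _truncate_lifetable(lt: LifeTable, omega: int) -> LifeTable:
    if omega == lt.omega:
        return lt
    if omega > lt.omega:
        raise InvalidArgumentError(
            f"omega={omega} exceeds the life table's terminal age {lt.omega}"
        )
    from .lifetable import build_lifetable_from_mx

    return build_lifetable_from_mx(
        lt.mx[: omega + 1],
        radix=lt.radix,
        a0_rule=lt.a0_rule,
        close_with_exposure=lt.closed_with_exposure,
        label=lt.label,
    )


COMPARE_MODES = ("time_change", "gender_gap")


def compare(summary_a: HealthSummary, summary_b: HealthSummary, mode: str) -> dict:
    """Signed differences a - b between two summaries.

    ``time_change`` pairs the same population and sex across years;
    ``gender_gap`` pairs the two sexes in the same population and year.
    Level differences are in years; ratio differences in percentage
    points.
    """
    if mode not in COMPARE_MODES:
        raise InvalidArgumentError(f"mode must be one of {COMPARE_MODES}, got {mode!r}")
    if mode == "time_change":
        if summary_a.population != summary_b.population or summary_a.sex != summary_b.sex:
            raise InvalidArgumentError(
                "time_change comparison requires matching population and sex; got "
                f"({summary_a.population!r}, {summary_a.sex!r}) vs "
                f"({summary_b.population!r}, {summary_b.sex!r})"
            )
    else:
        if summary_a.population != summary_b.population or summary_a.year != summary_b.year:
            raise InvalidArgumentError(
                "gender_gap comparison requires matching population and year; got "
                f"({summary_a.population!r}, {summary_a.year}) vs "
                f"({summary_b.population!r}, {summary_b.year})"
            )
    return {
        "mode": mode,
        "population": summary_a.population,
        "a": {"year": summary_a.year, "sex": summary_a.sex},
        "b": {"year": summary_b.year, "sex": summary_b.sex},
        "d_le": summary_a.le - summary_b.le,
        "d_he": summary_a.he - summary_b.he,
        "d_cal": summary_a.cal - summary_b.cal,
        "d_hcal": summary_a.hcal - summary_b.hcal,
        "d_ratio_he_le_pp": 100.0 * (summary_a.ratio_he_le - summary_b.ratio_he_le),
        "d_ratio_hcal_cal_pp": 100.0
        * (summary_a.ratio_hcal_cal - summary_b.ratio_hcal_cal),
    }
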