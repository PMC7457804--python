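"""Standard errors and confidence intervals for Sullivan-type measures.

Uncertainty is attributed entirely to the health-survey sampling; death
rates are treated as fixed.  Per-age prevalence variance uses the
binomial approximation Var(pi_x) = pi_x (1 - pi_x) / N_x with the
observed (unweighted) respondent count N_x, and the variance of a
Sullivan sum follows by treating ages as independent:

    Var(HE) = (1/l0^2) * sum_x L(x)^2 * Var(pi_x)

The identical formula with the diagonal person-years L_c(x) gives
Var(HCAL).  Smoothing induces correlation across ages which this
approximation ignores; the bootstrap in the test-suite quantifies how
far off that is on synthetic data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidArgumentError

__all__ = [
    "IntervalEstimate",
    "prevalence_variance",
    "schedule_variances",
    "sullivan_variance",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class IntervalEstimate:
    """A point estimate in years with its SE and normal 95% interval."""

    point: float
    se: float

    def __post_init__(self):
        if self.se < 0 or not np.isfinite(self.se):
            raise InvalidArgumentError(f"SE must be finite and >= 0, got {self.se}")

    @property
    def lower95(self) -> float:
        return self.point - Z95 * self.se

    @property
    def upper95(self) -> float:
        return self.point + Z95 * self.se

    def covers(self, truth: float) -> bool:
        return self.lower95 <= truth <= self.upper95


def prevalence_variance(pi, n):
    """Binomial variance pi(1-pi)/n of an age-specific proportion.

    Accepts scalars or arrays; every n must be >= 1.
    """
    pi = np.asarray(pi, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(pi < 0) or np.any(pi > 1):
        raise InvalidArgumentError("pi must lie in [0, 1]")
    if np.any(n < 1):
        raise InvalidArgumentError("sample size n must be >= 1")
    v = pi * (1.0 - pi) / n
    return v if v.ndim else float(v)


def schedule_variances(schedule) -> np.ndarray:
    """Per-age Var(pi) for a prevalence schedule.

    Uses the schedule's (typically smoothed) proportions with the
    observed per-age counts.  Ages with no respondents (N=0, i.e.
    values filled by extension or smoothing prediction) contribute zero
    variance, consistent with treating their proportions as carried
    over rather than estimated afresh.
    """
    var = np.zeros(len(schedule.ages))
    obs = schedule.n >= 1
    if np.any(obs):
        var[obs] = prevalence_variance(schedule.pi[obs], schedule.n[obs])
    return var


def sullivan_variance(person_years, radix: float, variances) -> float:
    """Variance of a Sullivan sum from per-age prevalence variances.

    Var = (1/radix^2) * sum_x person_years(x)^2 * Var(pi_x); pass a
    period life table's L(x) for Var(HE) or the diagonal L_c(x) for
    Var(HCAL).
    """
    L = np.asarray(person_years, dtype=float)
    v = np.asarray(variances, dtype=float)
    if radix <= 0:
        raise InvalidArgumentError(f"radix must be > 0, got {radix}")
    if L.shape != v.shape:
        raise InvalidArgumentError(
            f"age grid mismatch: person_years has {L.shape[0]} ages, "
            f"variances has {v.shape[0]}"
        )
    if np.any(v < 0):
        raise InvalidArgumentError("variances must be >= 0")
    return float(np.sum((L / radix) ** 2 * v))
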