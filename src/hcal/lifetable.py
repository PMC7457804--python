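"""Single-age period and cohort life tables.

All tables use one-year age intervals [x, x+1) for completed ages
0..omega, where omega is the (closed) terminal age.  Ages are integers
(age last birthday), calendar years are integers, and a death rate
m(x, t) is deaths per person-year lived in cell (x, t) of the Lexis
surface.

Two conventions are exposed because the source data never pins them
down:

* ``a0_rule`` — the separation factor a(0) for infants.  ``"keyfitz"``
  (default) uses a(0) = 0.07 + 1.7 * m(0), capped at 0.5;
  ``"constant_0.3"`` uses a fixed 0.3.  All other ages use a(x) = 0.5.
* terminal closure — the open-ended person-years at the terminal age.
  With ``close_with_exposure=True`` (default) L(omega) = l(omega) /
  m(omega) when m(omega) > 0 (the stationary-population identity), else
  0.  With ``close_with_exposure=False`` the table is truncated at
  exact age omega: L(omega) = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidArgumentError, MissingDataError

logger = logging.getLogger(__name__)

A0_RULES = ("keyfitz", "constant_0.3")

__all__ = [
    "A0_RULES",
    "MortalitySurface",
    "LifeTable",
    "mx_to_qx",
    "separation_factors",
    "build_lifetable_from_mx",
    "build_period_lifetable",
    "build_cohort_lifetable",
]


@dataclass(frozen=True)
class MortalitySurface:
    """Rectangular age x year grid of death rates.

    Parameters
    ----------
    ages
        Contiguous integer ages 0..omega.
    years
        Contiguous calendar years.
    rates
        Array of shape ``(len(ages), len(years))``; deaths per
        person-year.  ``NaN`` marks a missing cell (tolerated at
        construction when ``allow_missing=True``; any computation that
        needs the cell raises :class:`MissingDataError`).
    sex_label, source_label
        Free-text provenance.
    provenance
        Optional per-year-block provenance as ``(first_year, last_year,
        label)`` triples; populated by splicing.
    """

    ages: np.ndarray
    years: np.ndarray
    rates: np.ndarray
    sex_label: str = ""
    source_label: str = ""
    allow_missing: bool = False
    provenance: tuple = field(default_factory=tuple)

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=int)
        years = np.asarray(self.years, dtype=int)
        rates = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "rates", rates)
        if ages.ndim != 1 or years.ndim != 1:
            raise InvalidArgumentError("ages and years must be 1-D")
        if not np.array_equal(ages, np.arange(ages[0], ages[-1] + 1)):
            raise InvalidArgumentError("ages must be contiguous integers")
        if ages[0] != 0:
            raise InvalidArgumentError("age grid must start at 0")
        if len(ages) < 2:
            raise InvalidArgumentError("terminal age must be >= 1")
        if not np.array_equal(years, np.arange(years[0], years[-1] + 1)):
            raise InvalidArgumentError("years must be contiguous integers")
        if rates.shape != (len(ages), len(years)):
            raise InvalidArgumentError(
                f"rates shape {rates.shape} != (n_ages, n_years) = "
                f"({len(ages)}, {len(years)})"
            )
        finite = np.isfinite(rates)
        if np.any(finite & (rates < 0)):
            raise InvalidArgumentError("death rates must be >= 0")
        if not self.allow_missing and not finite.all():
            bad = np.argwhere(~finite)[0]
            raise InvalidArgumentError(
                f"non-finite rate at age {ages[bad[0]]}, year {years[bad[1]]} "
                "(pass allow_missing=True to keep NaN as missing markers)"
            )
        if self.allow_missing and np.any(np.isinf(rates)):
            raise InvalidArgumentError("death rates must be finite or NaN")

    @property
    def omega(self) -> int:
        return int(self.ages[-1])

    def year_index(self, year: int) -> int:
        if year < self.years[0] or year > self.years[-1]:
            raise MissingDataError(
                f"year {year} outside surface range "
                f"{self.years[0]}..{self.years[-1]}"
            )
        return int(year - self.years[0])

    def rate(self, age: int, year: int) -> float:
        """Death rate in Lexis cell (age, year)."""
        if age < 0 or age > self.omega:
            raise MissingDataError(f"age {age} outside 0..{self.omega}")
        r = float(self.rates[age, self.year_index(year)])
        if np.isnan(r):
            raise MissingDataError(f"missing death rate at (age {age}, year {year})")
        return r

    def period_rates(self, year: int) -> np.ndarray:
        """The full m(x) column for one calendar year."""
        col = self.rates[:, self.year_index(year)]
        if np.any(np.isnan(col)):
            bad = int(np.argwhere(np.isnan(col))[0][0])
            raise MissingDataError(
                f"missing death rate at (age {self.ages[bad]}, year {year})"
            )
        return col.copy()

    def diagonal_rates(self, birth_year: int) -> np.ndarray:
        """m(x) along the Lexis diagonal of the cohort born in `birth_year`.

        Requires the surface to contain years birth_year..birth_year+omega
        (the extinct-cohort requirement).
        """
        needed = np.arange(birth_year, birth_year + self.omega + 1)
        missing = [int(y) for y in needed if y < self.years[0] or y > self.years[-1]]
        if missing:
            raise MissingDataError(
                f"cohort {birth_year} needs years "
                f"{needed[0]}..{needed[-1]}; missing years {missing[0]}..{missing[-1]}"
            )
        idx = needed - self.years[0]
        diag = self.rates[self.ages, idx]
        if np.any(np.isnan(diag)):
            bad = int(np.argwhere(np.isnan(diag))[0][0])
            raise MissingDataError(
                f"missing death rate at (age {bad}, year {birth_year + bad}) "
                f"on the {birth_year} cohort diagonal"
            )
        return diag.copy()


def mx_to_qx(m, n: float = 1.0, a=0.5):
    """Convert a central death rate to a death probability.

    q = n*m / (1 + (n - a)*m), clamped to [0, 1].  ``a`` is the average
    person-years lived within the interval by those dying in it; the
    clamp is logged rather than raised because observed rates at extreme
    ages can exceed the formula's valid range.

    Accepts scalars or arrays (broadcast together).
    """
    m = np.asarray(m, dtype=float)
    a = np.asarray(a, dtype=float)
    if np.any(~np.isfinite(m)) or np.any(m < 0):
        raise InvalidArgumentError("death rate m must be finite and >= 0")
    if n <= 0:
        raise InvalidArgumentError(f"interval width n must be > 0, got {n}")
    if np.any(a <= 0) or np.any(a > n):
        raise InvalidArgumentError(f"separation factor a must lie in (0, n={n}]")
    q = n * m / (1.0 + (n - a) * m)
    if np.any(q > 1.0):
        logger.warning(
            "mx_to_qx: %d death probabilities clamped to 1 (max raw q=%.4g)",
            int(np.sum(q > 1.0)),
            float(np.max(q)),
        )
    q = np.clip(q, 0.0, 1.0)
    return q if q.ndim else float(q)


def separation_factors(mx: np.ndarray, a0_rule: str = "keyfitz") -> np.ndarray:
    """a(x) for a single-age table: 0.5 everywhere except infancy."""
    if a0_rule not in A0_RULES:
        raise InvalidArgumentError(f"a0_rule must be one of {A0_RULES}, got {a0_rule!r}")
    ax = np.full(len(mx), 0.5)
    if a0_rule == "keyfitz":
        ax[0] = min(0.07 + 1.7 * float(mx[0]), 0.5)
    else:
        ax[0] = 0.3
    return ax


@dataclass(frozen=True)
class LifeTable:
    """A complete single-decrement life table over ages 0..omega."""

    ages: np.ndarray
    mx: np.ndarray
    qx: np.ndarray
    ax: np.ndarray
    lx: np.ndarray
    dx: np.ndarray
    Lx: np.ndarray
    Tx: np.ndarray
    ex: np.ndarray
    radix: float
    a0_rule: str = "keyfitz"
    closed_with_exposure: bool = True
    label: str = ""

    @property
    def omega(self) -> int:
        return int(self.ages[-1])

    @property
    def e0(self) -> float:
        """Life expectancy at birth."""
        return float(self.ex[0])

    def survivorship(self) -> np.ndarray:
        """l(x) / l(0), the survival function on the radix-1 scale."""
        return self.lx / self.radix

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "age": self.ages,
                "mx": self.mx,
                "qx": self.qx,
                "ax": self.ax,
                "lx": self.lx,
                "dx": self.dx,
                "Lx": self.Lx,
                "Tx": self.Tx,
                "ex": self.ex,
            }
        )


def build_lifetable_from_mx(
    mx,
    radix: float = 1.0,
    a0_rule: str = "keyfitz",
    close_with_exposure: bool = True,
    label: str = "",
) -> LifeTable:
    """Build a life table from a vector of single-age death rates.

    The last element of ``mx`` is the terminal-age rate; q at the
    terminal age is forced to 1 and L(omega) follows the closure
    convention (see module docstring).
    """
    mx = np.asarray(mx, dtype=float)
    if mx.ndim != 1 or len(mx) < 2:
        raise InvalidArgumentError("mx must be a 1-D vector over ages 0..omega, omega>=1")
    if np.any(np.isnan(mx)):
        bad = int(np.argwhere(np.isnan(mx))[0][0])
        raise MissingDataError(f"missing death rate at age {bad}")
    if radix <= 0:
        raise InvalidArgumentError(f"radix must be > 0, got {radix}")
    ax = separation_factors(mx, a0_rule)
    qx = mx_to_qx(mx, 1.0, ax)
    qx = np.atleast_1d(qx).copy()
    qx[-1] = 1.0

    lx = np.empty_like(mx)
    lx[0] = radix
    lx[1:] = radix * np.cumprod(1.0 - qx[:-1])
    dx = np.empty_like(lx)
    dx[:-1] = lx[:-1] - lx[1:]
    dx[-1] = lx[-1]
    Lx = np.empty_like(lx)
    Lx[:-1] = lx[1:] + ax[:-1] * dx[:-1]
    if close_with_exposure and mx[-1] > 0:
        with np.errstate(over="ignore"):
            L_term = lx[-1] / mx[-1]
        # a vanishing terminal rate makes the open interval diverge;
        # fall back to the m=0 convention rather than propagate inf
        Lx[-1] = L_term if np.isfinite(L_term) else 0.0
    else:
        Lx[-1] = 0.0
    Tx = np.cumsum(Lx[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        ex = np.where(lx > 0, Tx / lx, 0.0)
    return LifeTable(
        ages=np.arange(len(mx)),
        mx=mx.copy(),
        qx=qx,
        ax=ax,
        lx=lx,
        dx=dx,
        Lx=Lx,
        Tx=Tx,
        ex=ex,
        radix=float(radix),
        a0_rule=a0_rule,
        closed_with_exposure=close_with_exposure,
        label=label,
    )


def build_period_lifetable(
    surface: MortalitySurface,
    year: int,
    radix: float = 1.0,
    a0_rule: str = "keyfitz",
    close_with_exposure: bool = True,
) -> LifeTable:
    """Period life table for one calendar year of a mortality surface."""
    mx = surface.period_rates(year)
    return build_lifetable_from_mx(
        mx,
        radix=radix,
        a0_rule=a0_rule,
        close_with_exposure=close_with_exposure,
        label=f"period {year} {surface.sex_label}".strip(),
    )


def build_cohort_lifetable(
    surface: MortalitySurface,
    birth_year: int,
    radix: float = 1.0,
    a0_rule: str = "keyfitz",
    close_with_exposure: bool = True,
) -> LifeTable:
    """Real-cohort life table read along the Lexis diagonal.

    m(x) is taken from cell (x, birth_year + x); the surface must span
    the cohort's whole life (years birth_year..birth_year+omega).
    """
    mx = surface.diagonal_rates(birth_year)
    return build_lifetable_from_mx(
        mx,
        radix=radix,
        a0_rule=a0_rule,
        close_with_exposure=close_with_exposure,
        label=f"cohort {birth_year} {surface.sex_label}".strip(),
    )
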