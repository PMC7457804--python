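"""Age-specific prevalence of activity limitation: tabulation and smoothing.

Survey microdata (one record per respondent: integer age, binary
unhealthy indicator, positive sampling weight) are tabulated into raw
weighted proportions per single age, then smoothed with penalized
B-splines (P-splines) under a *binomial* likelihood: the number of
unhealthy respondents at each age is treated as a binomial count with
the age's total as the number of trials.  Smoothing can be
one-dimensional (over age, one survey year at a time) or
two-dimensional (a tensor-product surface over age and survey year) for
series without breaks.

The binomial family is the exact likelihood for a proportion; for small
prevalence it coincides with treating the counts as Poisson, which is
the convention of count-smoothing packages in this area.

Defaults: cubic B-splines with a knot every 5 ages (every 5 years in
the year dimension), a second-order difference penalty on adjacent
spline coefficients, and the penalty chosen by BIC over a log-spaced
grid 1e-2..1e4 (13 points).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.special import expit, logit

from .errors import ConvergenceError, InvalidArgumentError, MissingDataError

__all__ = [
    "SurveySample",
    "PrevalenceSchedule",
    "tabulate_prevalence",
    "smooth_prevalence",
    "DEFAULT_LAMBDA_GRID",
]

DEFAULT_LAMBDA_GRID = tuple(np.logspace(-2, 4, 13))
_EPS = 1e-6


@dataclass(frozen=True)
class SurveySample:
    """Individual survey records for one year and population.

    ``data`` holds columns ``age`` (integer completed years),
    ``unhealthy`` (0/1) and ``weight`` (> 0).
    """

    data: pd.DataFrame
    year: int
    population: str = ""

    def __post_init__(self):
        df = self.data
        for col in ("age", "unhealthy", "weight"):
            if col not in df.columns:
                raise InvalidArgumentError(f"survey data lacks column {col!r}")
        if len(df) == 0:
            raise InvalidArgumentError("survey sample is empty")
        if not np.all(np.isin(df["unhealthy"], (0, 1))):
            raise InvalidArgumentError("unhealthy must be binary 0/1")
        if np.any(df["weight"] <= 0) or np.any(~np.isfinite(df["weight"])):
            raise InvalidArgumentError("weights must be positive and finite")
        if np.any(df["age"] < 0) or np.any(df["age"] != df["age"].astype(int)):
            raise InvalidArgumentError("ages must be non-negative integers")


@dataclass(frozen=True)
class PrevalenceSchedule:
    """pi(x): proportion unhealthy per single age, for one reference year.

    ``n`` is the unweighted respondent count per age (drives the
    standard-error approximation); ages with no respondents carry
    ``pi = NaN`` and ``n = 0`` until filled by smoothing or extension.
    ``metadata`` records how the schedule was produced (smoothing
    dimension, penalties, extension rules).
    """

    year: int
    ages: np.ndarray
    pi: np.ndarray
    n: np.ndarray
    population: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=int)
        pi = np.asarray(self.pi, dtype=float)
        n = np.asarray(self.n, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "pi", pi)
        object.__setattr__(self, "n", n)
        if not np.array_equal(ages, np.arange(ages[0], ages[-1] + 1)):
            raise InvalidArgumentError("prevalence age grid must be contiguous")
        if len(pi) != len(ages) or len(n) != len(ages):
            raise InvalidArgumentError("ages, pi and n must share one grid")
        obs = ~np.isnan(pi)
        if np.any(pi[obs] < 0) or np.any(pi[obs] > 1):
            raise InvalidArgumentError("prevalence must lie in [0, 1]")
        if np.any(n < 0):
            raise InvalidArgumentError("per-age sample sizes must be >= 0")

    def extend_to(self, ages, below: str = "constant") -> "PrevalenceSchedule":
        """Return a schedule covering ``ages`` (e.g. 0..omega).

        Ages below the youngest observed age take the youngest observed
        value (``below="constant"``, the least-assumption default) or 0
        (``below="zero"``); ages above the oldest observed age hold the
        oldest value.  Extended ages get n = 0.  Interior missing ages
        (NaN within the observed range) raise: fill them by smoothing
        first.
        """
        if below not in ("constant", "zero"):
            raise InvalidArgumentError("below must be 'constant' or 'zero'")
        ages = np.asarray(ages, dtype=int)
        if np.any(np.isnan(self.pi)):
            bad = self.ages[np.isnan(self.pi)]
            raise MissingDataError(
                f"prevalence missing at ages {bad.tolist()}; smooth before extending"
            )
        lo, hi = int(self.ages[0]), int(self.ages[-1])
        pi = np.empty(len(ages))
        n = np.zeros(len(ages))
        for i, x in enumerate(ages):
            if x < lo:
                pi[i] = 0.0 if below == "zero" else self.pi[0]
            elif x > hi:
                pi[i] = self.pi[-1]
            else:
                pi[i] = self.pi[x - lo]
                n[i] = self.n[x - lo]
        meta = dict(self.metadata)
        meta.update(
            extended_below=below if ages[0] < lo else None,
            extended_above="constant" if ages[-1] > hi else None,
            observed_age_range=(lo, hi),
        )
        return PrevalenceSchedule(
            year=self.year, ages=ages, pi=pi, n=n,
            population=self.population, metadata=meta,
        )

    def with_pi(self, pi, **meta) -> "PrevalenceSchedule":
        md = dict(self.metadata)
        md.update(meta)
        return replace(self, pi=np.asarray(pi, dtype=float), metadata=md)


def tabulate_prevalence(sample: SurveySample, age_range=None) -> PrevalenceSchedule:
    """Weighted raw prevalence per single age.

    pi(x) = (sum of weights of unhealthy respondents at age x) /
    (sum of all weights at age x); N(x) is the unweighted count.  Ages
    in the range with no respondents are flagged missing (NaN, N=0).
    """
    df = sample.data
    if age_range is None:
        age_range = (int(df["age"].min()), int(df["age"].max()))
    lo, hi = int(age_range[0]), int(age_range[1])
    if hi < lo:
        raise InvalidArgumentError(f"empty age range {lo}..{hi}")
    sub = df[(df["age"] >= lo) & (df["age"] <= hi)]
    if len(sub) == 0:
        raise InvalidArgumentError(f"no survey records in age range {lo}..{hi}")
    ages = np.arange(lo, hi + 1)
    wsum = sub.groupby("age")["weight"].sum()
    wbad = sub.assign(wu=sub["weight"] * sub["unhealthy"]).groupby("age")["wu"].sum()
    count = sub.groupby("age").size()
    pi = np.full(len(ages), np.nan)
    n = np.zeros(len(ages))
    for i, x in enumerate(ages):
        if x in wsum.index:
            pi[i] = wbad.loc[x] / wsum.loc[x]
            n[i] = count.loc[x]
    return PrevalenceSchedule(
        year=sample.year,
        ages=ages,
        pi=pi,
        n=n,
        population=sample.population,
        metadata={"kind": "raw_weighted"},
    )


# ---------------------------------------------------------------------------
# P-spline machinery


def _bspline_basis(x: np.ndarray, knot_spacing: float, degree: int = 3) -> np.ndarray:
    """Design matrix of a B-spline basis over the range of x.

    For spans of at least two knot intervals the knots are equally
    spaced and extended ``degree`` intervals beyond each boundary (no
    clamping), so the null space of a second-order difference penalty
    on the coefficients is exactly the straight lines in x.  Short
    spans fall back to a clamped low-order basis that saturates the
    observed points.
    """
    x = np.asarray(x, dtype=float)
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        return np.ones((len(x), 1))
    degree = min(degree, max(1, len(np.unique(x)) - 1))
    span = hi - lo
    if span < 2 * knot_spacing:
        t = np.concatenate([np.full(degree + 1, lo), np.full(degree + 1, hi)])
    else:
        m = int(np.ceil(span / knot_spacing))
        t = lo + knot_spacing * np.arange(-degree, m + degree + 1)
    return BSpline.design_matrix(x, t, degree, extrapolate=False).toarray()


def _diff_penalty(k: int, order: int = 2) -> np.ndarray:
    """D'D for the difference penalty of the given order on k coefficients."""
    if k <= order:
        return np.zeros((k, k))
    D = np.diff(np.eye(k), n=order, axis=0)
    return D.T @ D


def _binomial_deviance(y, n, mu):
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        t2 = np.where(n - y > 0, (n - y) * np.log((n - y) / (n - mu)), 0.0)
    return 2.0 * float(np.sum(t1 + t2))


def _pirls(B, y, n, P, max_iter=100, tol=1e-9):
    """Penalized IRLS for a binomial GLM with logit link.

    Returns (theta, edf, deviance).  ``y`` are unhealthy counts, ``n``
    totals (may be non-integer for weighted counts), ``P`` the penalty
    matrix added to the information.
    """
    p0 = (y + 0.5) / (n + 1.0)
    eta = logit(np.clip(p0, 1e-4, 1 - 1e-4))
    theta = None
    dev_old = np.inf
    for _ in range(max_iter):
        p = expit(eta)
        mu = n * p
        w = np.maximum(n * p * (1 - p), 1e-10)
        z = eta + (y - mu) / w
        BW = B.T * w
        A = BW @ B + P
        theta = np.linalg.solve(A, BW @ z)
        eta = B @ theta
        dev = _binomial_deviance(y, n, n * expit(eta))
        if abs(dev - dev_old) < tol * (abs(dev) + 1.0):
            w = np.maximum(n * expit(eta) * (1 - expit(eta)), 1e-10)
            BW = B.T * w
            A = BW @ B + P
            edf = float(np.trace(np.linalg.solve(A, BW @ B)))
            return theta, edf, dev
        dev_old = dev
    raise ConvergenceError(
        f"penalized IRLS did not converge in {max_iter} iterations "
        f"(last deviance {dev_old:.6g}, n_obs={len(y)}, n_coef={B.shape[1]})"
    )


def _fit_1d(ages, y, n, lambda_grid, knot_spacing, fixed_lambda=None):
    obs = n > 0
    if not np.any(obs):
        raise InvalidArgumentError("all per-age totals are zero; nothing to smooth")
    B_full = _bspline_basis(np.asarray(ages, dtype=float), knot_spacing)
    B = B_full[obs]
    Pen = _diff_penalty(B.shape[1])
    yo, no = y[obs], n[obs]
    if fixed_lambda is not None:
        lam = float(fixed_lambda)
        theta, edf, dev = _pirls(B, yo, no, lam * Pen)
        bic = dev + np.log(obs.sum()) * edf
    else:
        best = None
        for lam_try in lambda_grid:
            theta_t, edf_t, dev_t = _pirls(B, yo, no, lam_try * Pen)
            bic_t = dev_t + np.log(obs.sum()) * edf_t
            if best is None or bic_t < best[0]:
                best = (bic_t, lam_try, theta_t, edf_t)
        bic, lam, theta, edf = best
    pi_fit = np.clip(expit(B_full @ theta), _EPS, 1 - _EPS)
    return pi_fit, {"lambda_age": float(lam), "edf": edf, "bic": float(bic)}


def _fit_2d(ages, years, y, n, lambda_grid, knot_spacing, fixed_lambdas=None):
    """Tensor-product P-spline over (age, year); y, n shaped (n_ages, n_years)."""
    ages = np.asarray(ages, dtype=float)
    years = np.asarray(years, dtype=float)
    Bx = _bspline_basis(ages, knot_spacing)
    By = _bspline_basis(years, knot_spacing, degree=min(3, len(years) - 1))
    Kx, Ky = Bx.shape[1], By.shape[1]
    B_full = np.kron(By, Bx)  # rows ordered (year, age): age fastest
    yv = y.T.ravel()
    nv = n.T.ravel()
    obs = nv > 0
    if not np.any(obs):
        raise InvalidArgumentError("all totals are zero; nothing to smooth")
    B = B_full[obs]
    Px = np.kron(np.eye(Ky), _diff_penalty(Kx))
    Py = np.kron(_diff_penalty(Ky), np.eye(Kx))
    yo, no = yv[obs], nv[obs]
    n_obs = int(obs.sum())

    def fit(lx, ly):
        theta, edf, dev = _pirls(B, yo, no, lx * Px + ly * Py)
        return theta, edf, dev + np.log(n_obs) * edf

    if fixed_lambdas is not None:
        lx, ly = (float(v) for v in fixed_lambdas)
        theta, edf, bic = fit(lx, ly)
    else:
        best = None
        for lx_try in lambda_grid:
            for ly_try in lambda_grid:
                theta_t, edf_t, bic_t = fit(lx_try, ly_try)
                if best is None or bic_t < best[0]:
                    best = (bic_t, lx_try, ly_try, theta_t, edf_t)
        bic, lx, ly, theta, edf = best
    pi_fit = np.clip(expit(B_full @ theta), _EPS, 1 - _EPS)
    # back to (age, year) layout
    return pi_fit.reshape(len(years), len(ages)).T, {
        "lambda_age": float(lx),
        "lambda_year": float(ly),
        "edf": edf,
        "bic": float(bic),
    }


def smooth_prevalence(
    ages,
    n_unhealthy,
    n_total,
    years=None,
    year: int | None = None,
    dimension: str = "age_1d",
    penalty_selection: str = "bic",
    penalty=None,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    knot_spacing: float = 5.0,
    population: str = "",
):
    """Fit smooth single-age prevalence from unhealthy/total counts.

    Parameters
    ----------
    ages
        Contiguous integer ages.
    n_unhealthy, n_total
        1-D arrays over ages (``dimension="age_1d"``) or 2-D arrays of
        shape (n_ages, n_years) (``dimension="age_year_2d"``).  Counts
        may be non-integer (weighted); 0 <= n_unhealthy <= n_total.
        Ages (or cells) with zero total are treated as missing and
        predicted from the fit.
    years, year
        Year labels: ``years`` for the 2-D fit, ``year`` for 1-D.
    penalty_selection
        ``"bic"`` (grid search, default) or ``"fixed"`` with
        ``penalty`` a scalar (1-D) or an (age, year) pair (2-D).

    Returns
    -------
    PrevalenceSchedule (1-D) or list of PrevalenceSchedule, one per
    year (2-D), each carrying the fitted pi, the observed N(x), and the
    smoothing metadata.
    """
    ages = np.asarray(ages, dtype=int)
    if not np.array_equal(ages, np.arange(ages[0], ages[-1] + 1)):
        raise InvalidArgumentError("ages must be contiguous")
    y = np.asarray(n_unhealthy, dtype=float)
    n = np.asarray(n_total, dtype=float)
    if y.shape != n.shape:
        raise InvalidArgumentError("n_unhealthy and n_total must share a shape")
    if np.any(n < 0) or np.any(y < 0) or np.any(y > n + 1e-9):
        raise InvalidArgumentError("need 0 <= n_unhealthy <= n_total")
    if penalty_selection not in ("bic", "fixed"):
        raise InvalidArgumentError("penalty_selection must be 'bic' or 'fixed'")
    fixed = penalty if penalty_selection == "fixed" else None
    if penalty_selection == "fixed" and penalty is None:
        raise InvalidArgumentError("penalty_selection='fixed' needs a penalty value")

    if dimension == "age_1d":
        if y.ndim != 1 or len(y) != len(ages):
            raise InvalidArgumentError("1-D smoothing needs counts per age")
        pi_fit, meta = _fit_1d(ages, y, n, lambda_grid, knot_spacing, fixed)
        meta["dimension"] = "age_1d"
        return PrevalenceSchedule(
            year=int(year) if year is not None else 0,
            ages=ages,
            pi=pi_fit,
            n=n,
            population=population,
            metadata=meta,
        )
    elif dimension == "age_year_2d":
        if years is None:
            raise InvalidArgumentError("2-D smoothing needs the years axis")
        years = np.asarray(years, dtype=int)
        if y.ndim != 2 or y.shape != (len(ages), len(years)):
            raise InvalidArgumentError(
                "2-D smoothing needs counts shaped (n_ages, n_years)"
            )
        pi_fit, meta = _fit_2d(ages, years, y, n, lambda_grid, knot_spacing, fixed)
        meta["dimension"] = "age_year_2d"
        return [
            PrevalenceSchedule(
                year=int(yr),
                ages=ages,
                pi=pi_fit[:, j],
                n=n[:, j],
                population=population,
                metadata=dict(meta),
            )
            for j, yr in enumerate(years)
        ]
    raise InvalidArgumentError(
        f"dimension must be 'age_1d' or 'age_year_2d', got {dimension!r}"
    )
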