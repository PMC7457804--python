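"""Readers and writers for mortality surfaces, prevalence and results.

Supported formats (documented in docs/formats.md):

* national-statistics rate files in the ``Mx_1x1`` layout (header
  lines, then whitespace-separated columns Year, Age, Female, Male,
  Total; age ``110+`` for the open group; ``.`` for missing) — read
  only;
* long-form surface CSV ``year,age,rate`` — the package's native
  interchange, read/write;
* prevalence CSVs: microdata ``age,year,unhealthy,weight`` or
  tabulated ``age,year,n_unhealthy,n_total``; smoothed output
  ``age,year,pi_raw,pi_smooth,n``;
* HealthSummary records as flat CSV / JSON.

All readers are strict: a non-numeric cell is a parse error, never a
silent coercion, and every emitted CSV re-parses to an equal in-memory
object.
"""

from __future__ import annotations

import json

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError, ParseError
from .lifetable import LifeTable, MortalitySurface
from .prevalence import PrevalenceSchedule, SurveySample
from .sullivan import HealthSummary

__all__ = [
    "read_hmd_mx",
    "read_surface_csv",
    "write_surface_csv",
    "splice_surfaces",
    "read_survey_csv",
    "read_tabulated_csv",
    "write_prevalence_csv",
    "write_lifetable_csv",
    "write_summaries_csv",
    "write_summaries_json",
    "read_summaries_json",
]

_MX_COLUMNS = ["Year", "Age", "Female", "Male", "Total"]
_FLOAT_FMT = "%.12g"


def read_hmd_mx(path, sex: str = "Male", omega: int = 100) -> MortalitySurface:
    """Read one sex column of an ``Mx_1x1`` death-rate file.

    The open age group ``110+`` (and any age above ``omega``) is folded
    into the terminal age: the terminal rate is the rate reported at
    age ``omega``, which approximates the open-interval rate when
    exposures are unavailable.  ``.`` cells become missing markers
    (NaN) that downstream computations refuse to use silently.
    """
    if sex not in ("Female", "Male", "Total"):
        raise InvalidArgumentError(f"sex must be Female, Male or Total, got {sex!r}")
    rows = []
    header_seen = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if not header_seen:
                if tokens == _MX_COLUMNS:
                    header_seen = True
                continue
            if len(tokens) != 5:
                raise ParseError(
                    f"{path}: line {lineno}: expected 5 columns "
                    f"(Year Age Female Male Total), got {len(tokens)}"
                )
            year_s, age_s = tokens[0], tokens[1]
            try:
                year = int(year_s)
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: bad year {year_s!r}") from None
            if age_s.endswith("+"):
                age_s = age_s[:-1]
            try:
                age = int(age_s)
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: bad age {tokens[1]!r}") from None
            values = []
            for tok in tokens[2:]:
                if tok == ".":
                    values.append(np.nan)
                else:
                    try:
                        values.append(float(tok))
                    except ValueError:
                        raise ParseError(
                            f"{path}: line {lineno}: bad rate {tok!r}"
                        ) from None
            rows.append((year, age, *values))
    if not header_seen:
        raise ParseError(f"{path}: no 'Year Age Female Male Total' header line found")
    if not rows:
        raise ParseError(f"{path}: no data rows after the header")
    df = pd.DataFrame(rows, columns=["year", "age"] + _MX_COLUMNS[2:])
    df = df[df["age"] <= omega]
    try:
        wide = df.pivot(index="age", columns="year", values=sex)
    except ValueError as exc:
        raise ParseError(f"{path}: duplicate (year, age) rows: {exc}") from exc
    years = np.array(sorted(df["year"].unique()))
    ages = np.arange(omega + 1)
    missing_ages = set(ages) - set(wide.index)
    if missing_ages:
        raise ParseError(
            f"{path}: ages {sorted(missing_ages)[:5]}... absent; "
            f"need every age 0..{omega}"
        )
    rates = wide.reindex(index=ages, columns=years).to_numpy(dtype=float)
    return MortalitySurface(
        ages=ages,
        years=years,
        rates=rates,
        sex_label=sex,
        source_label=str(path),
        allow_missing=True,
        provenance=((int(years[0]), int(years[-1]), str(path)),),
    )


def write_surface_csv(surface: MortalitySurface, path) -> None:
    """Write the long-form ``year,age,rate`` interchange CSV."""
    years = np.repeat(surface.years, len(surface.ages))
    ages = np.tile(surface.ages, len(surface.years))
    rates = surface.rates.T.ravel()
    pd.DataFrame({"year": years, "age": ages, "rate": rates}).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_surface_csv(path, sex_label: str = "", source_label: str = "") -> MortalitySurface:
    """Read the long-form ``year,age,rate`` CSV back into a surface."""
    try:
        df = pd.read_csv(path, dtype={"year": int, "age": int, "rate": float})
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    for col in ("year", "age", "rate"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    years = np.array(sorted(df["year"].unique()))
    ages = np.array(sorted(df["age"].unique()))
    wide = df.pivot_table(index="age", columns="year", values="rate", aggfunc="first")
    if wide.isna().any().any() or len(df) != len(years) * len(ages):
        raise ParseError(f"{path}: surface grid is not rectangular/complete")
    return MortalitySurface(
        ages=ages,
        years=years,
        rates=wide.reindex(index=ages, columns=years).to_numpy(dtype=float),
        sex_label=sex_label,
        source_label=source_label or str(path),
    )


def splice_surfaces(
    older: MortalitySurface, newer: MortalitySurface, cut_year: int
) -> MortalitySurface:
    """Concatenate two surfaces at ``cut_year``.

    Years before the cut come from ``older``, years from the cut on
    from ``newer``; the age grids must match exactly, and the two
    pieces must meet with neither a gap nor an ambiguity at the cut.
    Per-block provenance is retained on the result.
    """
    if not np.array_equal(older.ages, newer.ages):
        raise InvalidArgumentError(
            f"age grids differ: 0..{older.omega} vs 0..{newer.omega}"
        )
    if older.years[-1] < cut_year - 1:
        raise InvalidArgumentError(
            f"gap at cut: older surface ends {older.years[-1]}, cut at {cut_year}"
        )
    if newer.years[0] > cut_year:
        raise InvalidArgumentError(
            f"gap at cut: newer surface starts {newer.years[0]}, cut at {cut_year}"
        )
    if older.years[0] > cut_year - 1:
        raise InvalidArgumentError(
            f"older surface ({older.years[0]}..{older.years[-1]}) has no years "
            f"before the cut {cut_year}"
        )
    old_mask = older.years < cut_year
    new_mask = newer.years >= cut_year
    years = np.concatenate([older.years[old_mask], newer.years[new_mask]])
    rates = np.concatenate(
        [older.rates[:, old_mask], newer.rates[:, new_mask]], axis=1
    )
    prov = tuple(
        (max(b[0], int(years[0])), min(b[1], cut_year - 1), b[2])
        for b in (older.provenance or ((int(older.years[0]), int(older.years[-1]), older.source_label),))
        if b[0] <= cut_year - 1
    ) + tuple(
        (max(b[0], cut_year), b[1], b[2])
        for b in (newer.provenance or ((int(newer.years[0]), int(newer.years[-1]), newer.source_label),))
        if b[1] >= cut_year
    )
    return MortalitySurface(
        ages=older.ages,
        years=years,
        rates=rates,
        sex_label=older.sex_label or newer.sex_label,
        source_label=f"{older.source_label}+{newer.source_label}",
        allow_missing=older.allow_missing or newer.allow_missing,
        provenance=prov,
    )


# ---------------------------------------------------------------------------
# Prevalence I/O


def read_survey_csv(path, year: int | None = None, population: str = "") -> list[SurveySample]:
    """Read microdata ``age,year,unhealthy,weight``; one sample per year."""
    try:
        df = pd.read_csv(
            path, dtype={"age": int, "year": int, "unhealthy": int, "weight": float}
        )
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    for col in ("age", "year", "unhealthy", "weight"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    if year is not None:
        df = df[df["year"] == year]
        if len(df) == 0:
            raise ParseError(f"{path}: no records for year {year}")
    return [
        SurveySample(
            data=g[["age", "unhealthy", "weight"]].reset_index(drop=True),
            year=int(yr),
            population=population,
        )
        for yr, g in df.groupby("year")
    ]


def read_tabulated_csv(path):
    """Read tabulated counts ``age,year,n_unhealthy,n_total``.

    Returns (ages, years, n_unhealthy, n_total) with count arrays of
    shape (n_ages, n_years).
    """
    try:
        df = pd.read_csv(
            path,
            dtype={"age": int, "year": int, "n_unhealthy": float, "n_total": float},
        )
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    for col in ("age", "year", "n_unhealthy", "n_total"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    ages = np.array(sorted(df["age"].unique()))
    years = np.array(sorted(df["year"].unique()))
    y = df.pivot_table(index="age", columns="year", values="n_unhealthy", aggfunc="first")
    n = df.pivot_table(index="age", columns="year", values="n_total", aggfunc="first")
    y = y.reindex(index=ages, columns=years).fillna(0.0).to_numpy(dtype=float)
    n = n.reindex(index=ages, columns=years).fillna(0.0).to_numpy(dtype=float)
    return ages, years, y, n


def write_prevalence_csv(schedules, path, raw=None) -> None:
    """Write ``age,year,pi_raw,pi_smooth,n`` for one or more schedules.

    ``raw`` optionally maps year -> raw PrevalenceSchedule on the same
    ages; pi_raw is empty where unavailable.
    """
    if isinstance(schedules, PrevalenceSchedule):
        schedules = [schedules]
    frames = []
    for s in schedules:
        pi_raw = np.full(len(s.ages), np.nan)
        if raw is not None and s.year in raw:
            r = raw[s.year]
            if np.array_equal(r.ages, s.ages):
                pi_raw = r.pi
        frames.append(
            pd.DataFrame(
                {
                    "age": s.ages,
                    "year": s.year,
                    "pi_raw": pi_raw,
                    "pi_smooth": s.pi,
                    "n": s.n,
                }
            )
        )
    pd.concat(frames).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_lifetable_csv(lt: LifeTable, path) -> None:
    lt.to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# Result records


def write_summaries_csv(summaries, path) -> None:
    rows = [s.to_dict() for s in summaries]
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_summaries_json(summaries, path) -> None:
    rows = [s.to_dict() for s in summaries]
    with open(path, "w") as fh:
        json.dump(rows, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_summaries_json(path) -> list[HealthSummary]:
    with open(path) as fh:
        rows = json.load(fh)
    return [HealthSummary.from_dict(r) for r in rows]
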