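import numpy as np
import pytest

from hcal import (
    HealthSummary,
    InvalidArgumentError,
    LifeTable,
    PrevalenceSchedule,
    build_period_lifetable,
    cal,
    compare,
    healthy_survival_curve,
    reconstruct_cohort_survivorship,
    sullivan_hcal,
    sullivan_he,
    summarize,
)


def make_schedule(ages, pi, n=None, year=2015):
    ages = np.asarray(ages)
    return PrevalenceSchedule(
        year=year,
        ages=ages,
        pi=np.asarray(pi, dtype=float),
        n=np.zeros(len(ages)) if n is None else np.asarray(n, dtype=float),
    )


def stub_lifetable(Lx, radix=1.0):
    """Minimal table carrying only what the Sullivan sum reads."""
    Lx = np.asarray(Lx, dtype=float)
    k = len(Lx)
    z = np.zeros(k)
    return LifeTable(
        ages=np.arange(k), mx=z, qx=z, ax=z, lx=np.full(k, radix),
        dx=z, Lx=Lx, Tx=z, ex=z, radix=radix,
    )


class TestHealthySurvivalCurve:
    def test_worked_example(self):
        """Survivorship 0.8 and prevalence 0.3 combine to 0.56."""
        curve = healthy_survival_curve(np.array([0.8]), np.array([0.3]))
        assert curve[0] == pytest.approx(0.56, abs=1e-12)

    def test_zero_prevalence_returns_survivorship(self, stationary_surface):
        cs = reconstruct_cohort_survivorship(stationary_surface, 2015)
        curve = healthy_survival_curve(cs, np.zeros(len(cs.ages)))
        assert np.array_equal(curve, cs.p_c)

    def test_full_prevalence_returns_zero(self, stationary_surface):
        cs = reconstruct_cohort_survivorship(stationary_surface, 2015)
        assert np.all(healthy_survival_curve(cs, np.ones(len(cs.ages))) == 0.0)

    def test_grid_mismatch_names_both_grids(self, stationary_surface):
        cs = reconstruct_cohort_survivorship(stationary_surface, 2015)
        sched = make_schedule(np.arange(16, 91), np.full(75, 0.2))
        with pytest.raises(InvalidArgumentError) as err:
            healthy_survival_curve(cs, sched)
        assert "0..100" in str(err.value) and "16..90" in str(err.value)


class TestSullivanSums:
    def test_zero_prevalence_gives_total_years(self, improving_surface, logistic_pi):
        lt = build_period_lifetable(improving_surface, 2015)
        cs = reconstruct_cohort_survivorship(improving_surface, 2015)
        zero = np.zeros(len(lt.ages))
        assert sullivan_he(lt, zero) == lt.e0
        assert sullivan_hcal(cs, zero) == cal(cs)

    def test_half_prevalence_halves_the_years(self, improving_surface):
        lt = build_period_lifetable(improving_surface, 2015)
        half = np.full(len(lt.ages), 0.5)
        assert sullivan_he(lt, half) == pytest.approx(lt.e0 / 2, abs=1e-12)

    def test_toy_hand_sum(self):
        lt = stub_lifetable([0.9, 0.7, 0.2])
        he = sullivan_he(lt, np.array([0.1, 0.2, 0.5]))
        assert he == pytest.approx(0.81 + 0.56 + 0.10, abs=1e-12)

    def test_stationary_he_equals_hcal(self, stationary_surface, logistic_pi):
        lt = build_period_lifetable(stationary_surface, 2015)
        cs = reconstruct_cohort_survivorship(stationary_surface, 2015)
        assert sullivan_he(lt, logistic_pi) == sullivan_hcal(cs, logistic_pi)

    def test_prevalence_dominance(self, improving_surface, logistic_pi):
        """Lower prevalence everywhere can only increase healthy years."""
        lt = build_period_lifetable(improving_surface, 2015)
        cs = reconstruct_cohort_survivorship(improving_surface, 2015)
        lower = logistic_pi * 0.8
        assert sullivan_he(lt, lower) >= sullivan_he(lt, logistic_pi)
        assert sullivan_hcal(cs, lower) >= sullivan_hcal(cs, logistic_pi)

    def test_bound_chain(self, improving_surface, logistic_pi):
        lt = build_period_lifetable(improving_surface, 2015)
        cs = reconstruct_cohort_survivorship(improving_surface, 2015)
        he = sullivan_he(lt, logistic_pi)
        hcal = sullivan_hcal(cs, logistic_pi)
        assert 0.0 <= he <= lt.e0
        assert 0.0 <= hcal <= cal(cs)

    def test_invalid_prevalence_rejected(self, improving_surface):
        lt = build_period_lifetable(improving_surface, 2015)
        bad = np.zeros(len(lt.ages))
        bad[50] = 1.5
        with pytest.raises(InvalidArgumentError):
            sullivan_he(lt, bad)


def test_relative_weighting_favours_hcal_ratio(improving_surface, logistic_pi):
    """With cohort survivorship relatively heavier at young ages and
    prevalence rising with age, HCAL/CAL exceeds HE/LE."""
    lt = build_period_lifetable(improving_surface, 2015)
    cs = reconstruct_cohort_survivorship(improving_surface, 2015)
    w_period = lt.Lx / lt.Tx[0]
    w_cohort = cs.L_c / np.sum(cs.L_c)
    rel = w_cohort / w_period
    premise = np.all(np.diff(rel) <= 1e-9) and np.all(np.diff(logistic_pi) >= 0)
    if not premise:
        pytest.skip(
            "relative-survivorship premise not met on this surface: "
            f"max d(rel)={np.max(np.diff(rel)):.3g}"
        )
    ratio_he = sullivan_he(lt, logistic_pi) / lt.e0
    ratio_hcal = sullivan_hcal(cs, logistic_pi) / cal(cs)
    assert ratio_hcal >= ratio_he


class TestHealthSummary:
    def test_ratios_equal_quotients(self):
        s = HealthSummary("X", 2014, "m", le=80.0, he=60.0, cal=75.0, hcal=58.0)
        assert s.ratio_he_le == 60.0 / 80.0
        assert s.ratio_hcal_cal == 58.0 / 75.0

    def test_bounds_enforced(self):
        with pytest.raises(InvalidArgumentError):
            HealthSummary("X", 2014, "m", le=80.0, he=81.0, cal=75.0, hcal=58.0)
        with pytest.raises(InvalidArgumentError):
            HealthSummary("X", 2014, "m", le=80.0, he=60.0, cal=75.0, hcal=76.0)

    def test_round_trips_through_dict(self):
        s = HealthSummary("X", 2014, "m", 80.0, 60.0, 75.0, 58.0, he_se=0.2, hcal_se=0.3)
        assert HealthSummary.from_dict(s.to_dict()) == s


class TestCompare:
    def two_summaries(self, surface, pi, years=(2014, 2008)):
        sched = make_schedule(np.arange(101), pi)
        return [
            summarize(surface, sched, y, population="synthetic", sex="m", with_se=False)
            for y in years
        ]

    def test_identical_summaries_give_zero(self, improving_surface, logistic_pi):
        a, _ = self.two_summaries(improving_surface, logistic_pi)
        rec = compare(a, a, "time_change")
        for key in ("d_le", "d_he", "d_cal", "d_hcal", "d_ratio_he_le_pp"):
            assert rec[key] == 0.0

    def test_time_change_matches_direct_recomputation(
        self, improving_surface, logistic_pi
    ):
        a, b = self.two_summaries(improving_surface, logistic_pi)
        rec = compare(a, b, "time_change")
        lt14 = build_period_lifetable(improving_surface, 2014)
        lt08 = build_period_lifetable(improving_surface, 2008)
        assert rec["d_le"] == pytest.approx(lt14.e0 - lt08.e0, abs=1e-12)
        assert rec["d_le"] > 0 and rec["d_cal"] > 0

    def test_mismatched_pairing_rejected(self, improving_surface, logistic_pi):
        a, b = self.two_summaries(improving_surface, logistic_pi)
        with pytest.raises(InvalidArgumentError):
            compare(a, b, "gender_gap")
        with pytest.raises(InvalidArgumentError):
            compare(a, b, "nonsense")
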