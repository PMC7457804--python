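import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from hcal import (
    InvalidArgumentError,
    MissingDataError,
    PrevalenceSchedule,
    SurveySample,
    smooth_prevalence,
    tabulate_prevalence,
)

AGES = np.arange(16, 91)


def logistic_curve(ages, floor=0.04, ceiling=0.7, mid=60.0, steep=0.09):
    return floor + (ceiling - floor) * expit(steep * (np.asarray(ages) - mid))


def sample_from(records, year=2014):
    df = pd.DataFrame(records, columns=["age", "unhealthy", "weight"])
    return SurveySample(data=df, year=year)


class TestTabulate:
    def test_weighted_proportion(self):
        sched = tabulate_prevalence(
            sample_from([(40, 1, 2.0), (40, 0, 1.0)]), age_range=(40, 40)
        )
        assert sched.pi[0] == pytest.approx(2 / 3, abs=1e-15)
        assert sched.n[0] == 2

    def test_all_healthy_gives_zero(self):
        sched = tabulate_prevalence(
            sample_from([(40, 0, 1.0), (41, 0, 2.5), (41, 0, 1.0)])
        )
        assert np.all(sched.pi[sched.n > 0] == 0.0)

    def test_equal_weights_match_unweighted_proportion(self):
        rng = np.random.default_rng(7)
        recs = [(int(a), int(u), 3.0) for a, u in
                zip(rng.integers(30, 35, 200), rng.random(200) < 0.4)]
        sched = tabulate_prevalence(sample_from(recs))
        df = pd.DataFrame(recs, columns=["age", "unhealthy", "weight"])
        expected = df.groupby("age")["unhealthy"].mean()
        for age, val in expected.items():
            assert sched.pi[age - sched.ages[0]] == pytest.approx(val, abs=1e-15)

    def test_empty_age_range_rejected(self):
        with pytest.raises(InvalidArgumentError):
            tabulate_prevalence(sample_from([(40, 1, 1.0)]), age_range=(50, 60))

    def test_gap_ages_flagged_missing(self):
        sched = tabulate_prevalence(
            sample_from([(40, 1, 1.0), (42, 0, 1.0)]), age_range=(40, 42)
        )
        assert np.isnan(sched.pi[1]) and sched.n[1] == 0


class TestExtend:
    def base(self):
        return PrevalenceSchedule(
            year=2014, ages=np.arange(16, 20), pi=[0.1, 0.2, 0.3, 0.4],
            n=[10, 10, 10, 10],
        )

    def test_constant_below_and_hold_above(self):
        full = self.base().extend_to(np.arange(0, 25))
        assert np.all(full.pi[:16] == 0.1)
        assert np.all(full.pi[20:] == 0.4)
        assert np.all(full.n[:16] == 0) and np.all(full.n[20:] == 0)
        assert full.metadata["observed_age_range"] == (16, 19)

    def test_zero_below_option(self):
        full = self.base().extend_to(np.arange(0, 20), below="zero")
        assert np.all(full.pi[:16] == 0.0)

    def test_interior_gap_refuses_extension(self):
        sched = PrevalenceSchedule(
            year=2014, ages=np.arange(16, 19), pi=[0.1, np.nan, 0.3], n=[5, 0, 5]
        )
        with pytest.raises(MissingDataError, match="17"):
            sched.extend_to(np.arange(0, 30))


class TestSmoothing:
    def test_constant_truth_recovered_with_large_samples(self):
        rng = np.random.default_rng(11)
        n = np.full(len(AGES), 100_000.0)
        y = rng.binomial(100_000, 0.3, size=len(AGES)).astype(float)
        sched = smooth_prevalence(AGES, y, n, year=2014)
        assert np.max(np.abs(sched.pi - 0.3)) < 0.01

    def test_logistic_truth_recovered_at_survey_scale(self):
        truth = logistic_curve(AGES)
        rng = np.random.default_rng(23)
        maes = []
        for _ in range(3):
            y = rng.binomial(500, truth).astype(float)
            sched = smooth_prevalence(AGES, y, np.full(len(AGES), 500.0), year=2014)
            maes.append(np.mean(np.abs(sched.pi - truth)))
        assert np.mean(maes) < 0.02

    def test_infinite_penalty_tends_to_linear_logit(self):
        """The second-difference penalty leaves a straight line on the link
        scale; the limit must agree with a plain logistic GLM in age."""
        sm = pytest.importorskip("statsmodels.api")
        truth = logistic_curve(AGES)
        rng = np.random.default_rng(3)
        n = np.full(len(AGES), 2000.0)
        y = rng.binomial(2000, truth).astype(float)
        sched = smooth_prevalence(
            AGES, y, n, year=2014, penalty_selection="fixed", penalty=1e9
        )
        X = np.column_stack([np.ones(len(AGES)), AGES])
        glm = sm.GLM(np.column_stack([y, n - y]), X, family=sm.families.Binomial())
        eta_glm = X @ glm.fit().params
        np.testing.assert_allclose(logit(sched.pi), eta_glm, atol=2e-3)

    def test_two_year_grid_2d_reduces_to_per_year_1d(self):
        ages = np.arange(16, 61)
        truth = np.column_stack([logistic_curve(ages), logistic_curve(ages, mid=58.0)])
        rng = np.random.default_rng(5)
        n = np.full(truth.shape, 800.0)
        y = rng.binomial(800, truth).astype(float)
        two_d = smooth_prevalence(
            ages, y, n, years=[2008, 2009], dimension="age_year_2d",
            penalty_selection="fixed", penalty=(10.0, 1e8),
        )
        for j, sched2 in enumerate(two_d):
            one_d = smooth_prevalence(
                ages, y[:, j], n[:, j], year=2008 + j,
                penalty_selection="fixed", penalty=10.0,
            )
            np.testing.assert_allclose(sched2.pi, one_d.pi, atol=1e-6)

    def test_smoother_is_idempotent_on_smooth_data(self):
        truth = logistic_curve(AGES)
        n = np.full(len(AGES), 100_000.0)
        sched = smooth_prevalence(AGES, truth * n, n, year=2014)
        assert np.max(np.abs(sched.pi - truth)) < 0.005

    def test_fit_stays_inside_unit_interval(self):
        rng = np.random.default_rng(9)
        y = rng.binomial(30, logistic_curve(AGES, floor=0.0, ceiling=0.98)).astype(float)
        sched = smooth_prevalence(AGES, y, np.full(len(AGES), 30.0), year=2014)
        assert np.all((sched.pi > 0) & (sched.pi < 1))

    def test_zero_total_ages_are_predicted(self):
        truth = logistic_curve(AGES)
        rng = np.random.default_rng(13)
        n = np.full(len(AGES), 1000.0)
        n[30:35] = 0.0
        y = np.where(n > 0, rng.binomial(1000, truth), 0.0)
        sched = smooth_prevalence(AGES, y, n, year=2014)
        assert np.all(np.abs(sched.pi[30:35] - truth[30:35]) < 0.05)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_total": np.zeros(len(AGES))},
            {"n_unhealthy": np.full(len(AGES), 10.0), "n_total": np.full(len(AGES), 5.0)},
            {"dimension": "bogus"},
        ],
    )
    def test_invalid_inputs_rejected(self, kwargs):
        base = {
            "ages": AGES,
            "n_unhealthy": np.full(len(AGES), 5.0),
            "n_total": np.full(len(AGES), 50.0),
            "year": 2014,
        }
        base.update(kwargs)
        with pytest.raises(InvalidArgumentError):
            smooth_prevalence(**base)
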