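"""Log-logistic machinery, thresholds and diagnostic-range construction."""

import numpy as np
import pytest
from scipy import integrate, stats

from glykit.cohort import (
    LogLogisticFit,
    build_range_table,
    central_interval,
    construct_range,
    equal_density_threshold,
    fit_loglogistic,
    ks_compare,
    roc_youden_threshold,
    tail_shift_test,
)
from glykit.errors import DegenerateDensitiesError, FittingError, ValidationError


def loglogistic_samples(alpha, beta, n, seed):
    return stats.fisk.rvs(c=beta, scale=alpha, size=n, random_state=seed)


class TestFitting:
    def test_mle_recovers_known_parameters(self):
        x = loglogistic_samples(1.0, 5.0, 10_000, seed=42)
        fit = fit_loglogistic(x)
        assert fit.scale == pytest.approx(1.0, rel=0.05)
        assert fit.shape == pytest.approx(5.0, rel=0.05)

    def test_median_equals_scale(self):
        fit = fit_loglogistic(loglogistic_samples(2.5, 3.0, 500, seed=1))
        assert fit.quantile(0.5) == pytest.approx(fit.scale, rel=1e-12)

    def test_degenerate_and_invalid_samples(self):
        with pytest.raises(FittingError):
            fit_loglogistic(np.ones(50))
        with pytest.raises(ValidationError):
            fit_loglogistic(np.array([1.0, -2.0] * 10))
        with pytest.raises(ValidationError):
            fit_loglogistic(np.ones(5))

    def test_quantile_cdf_round_trip(self):
        fit = LogLogisticFit(scale=2.0, shape=4.0, log_likelihood=0.0, n=1)
        p = np.linspace(0.01, 0.99, 99)
        np.testing.assert_allclose(fit.cdf(fit.quantile(p)), p, atol=1e-10)


class TestCentralInterval:
    def test_closed_form_interval(self):
        fit = LogLogisticFit(scale=1.0, shape=3.0, log_likelihood=0.0, n=1)
        lo, hi = central_interval(fit, 0.90)
        assert lo == pytest.approx(19.0 ** (-1.0 / 3.0), rel=1e-9)
        assert hi == pytest.approx(19.0 ** (1.0 / 3.0), rel=1e-9)
        assert (lo, hi) == pytest.approx((0.374756, 2.668402), rel=1e-5)

    def test_interval_mass_by_numeric_integration(self):
        fit = LogLogisticFit(scale=1.7, shape=2.2, log_likelihood=0.0, n=1)
        lo, hi = central_interval(fit, 0.90)
        mass, _ = integrate.quad(fit.pdf, lo, hi)
        assert mass == pytest.approx(0.90, abs=1e-6)

    def test_vanishing_mass_collapses_to_median(self):
        fit = LogLogisticFit(scale=3.0, shape=2.0, log_likelihood=0.0, n=1)
        lo, hi = central_interval(fit, 1e-9)
        assert lo == pytest.approx(3.0, rel=1e-4)
        assert hi == pytest.approx(3.0, rel=1e-4)

    def test_invalid_mass(self):
        fit = LogLogisticFit(scale=1.0, shape=1.0, log_likelihood=0.0, n=1)
        with pytest.raises(ValidationError):
            central_interval(fit, 1.0)


class TestKS:
    def test_identical_samples_have_zero_statistic(self):
        x = loglogistic_samples(1.0, 4.0, 200, seed=3)
        res = ks_compare(x, x)
        assert res.statistic == 0.0

    def test_strong_scale_shift_detected(self):
        a = loglogistic_samples(1.0, 4.0, 500, seed=5)
        b = loglogistic_samples(3.0, 4.0, 500, seed=6)
        assert ks_compare(a, b).p_value < 0.001

    def test_statistic_matches_brute_force_ecdf(self):
        a = loglogistic_samples(1.0, 3.0, 80, seed=7)
        b = loglogistic_samples(1.5, 3.0, 60, seed=8)
        res = ks_compare(a, b)
        pooled = np.concatenate([a, b])
        brute = max(
            abs(np.mean(a <= x) - np.mean(b <= x)) for x in pooled
        )
        assert res.statistic == pytest.approx(brute, abs=1e-12)


class TestTailShift:
    def test_same_distribution_gives_none(self):
        a = loglogistic_samples(1.0, 4.0, 500, seed=11)
        b = loglogistic_samples(1.0, 4.0, 500, seed=12)
        assert tail_shift_test(a, b) == "none"

    def test_scale_shift_direction_and_antisymmetry(self):
        a = loglogistic_samples(1.0, 4.0, 500, seed=13)
        b = 3.0 * loglogistic_samples(1.0, 4.0, 500, seed=14)
        assert tail_shift_test(a, b) == "right"
        # swapping which cohort carries the scale factor flips the direction
        assert tail_shift_test(b, a) == "left"


class TestEqualDensity:
    def test_identical_fits_rejected(self):
        f = LogLogisticFit(scale=1.0, shape=4.0, log_likelihood=0.0, n=1)
        with pytest.raises(DegenerateDensitiesError):
            equal_density_threshold(f, f)

    def test_matches_dense_grid_oracle(self):
        fh = LogLogisticFit(scale=1.0, shape=4.0, log_likelihood=0.0, n=1)
        fnh = LogLogisticFit(scale=3.0, shape=4.0, log_likelihood=0.0, n=1)
        thr = equal_density_threshold(fh, fnh)
        grid = np.arange(1.0, 3.0, 1e-4)
        oracle = grid[np.argmin(np.abs(fh.pdf(grid) - fnh.pdf(grid)))]
        assert thr == pytest.approx(oracle, abs=1e-4)

    def test_symmetric_in_the_two_fits(self):
        fh = LogLogisticFit(scale=1.0, shape=5.0, log_likelihood=0.0, n=1)
        fnh = LogLogisticFit(scale=2.0, shape=3.0, log_likelihood=0.0, n=1)
        assert equal_density_threshold(fh, fnh) == pytest.approx(
            equal_density_threshold(fnh, fh), rel=1e-9
        )


class TestYouden:
    def test_perfect_separation(self):
        thr, J, direction = roc_youden_threshold([0.2, 0.5, 0.9], [2.1, 2.5, 3.0])
        assert J == pytest.approx(1.0)
        assert 0.9 < thr < 2.1
        assert direction == "high"

    def test_no_information_when_samples_identical(self):
        x = loglogistic_samples(1.0, 4.0, 100, seed=21)
        _, J, _ = roc_youden_threshold(x, x)
        assert J <= 1.0 / len(x) + 1e-12

    def test_equals_exhaustive_enumeration(self):
        rng = np.random.default_rng(22)
        a = rng.lognormal(0.0, 0.5, 60)
        b = rng.lognormal(0.8, 0.5, 70)
        thr, J, direction = roc_youden_threshold(a, b)
        pooled = np.unique(np.concatenate([a, b]))
        cuts = 0.5 * (pooled[:-1] + pooled[1:])
        best = -np.inf
        for cut in cuts:
            for d in ("high", "low"):
                sens = np.mean(b > cut) if d == "high" else np.mean(b < cut)
                spec = np.mean(a <= cut) if d == "high" else np.mean(a >= cut)
                best = max(best, sens + spec - 1.0)
        assert J == pytest.approx(best, abs=1e-12)
        assert direction == "high"


class TestRangeConstruction:
    ALPHA_H, ALPHA_NH, SHAPE = 1.0, 3.0, 4.0

    def cohorts(self, n=800):
        return (
            loglogistic_samples(self.ALPHA_H, self.SHAPE, n, seed=31),
            loglogistic_samples(self.ALPHA_NH, self.SHAPE, n, seed=32),
        )

    def test_recovers_analytic_construction(self):
        """Boundaries land within 10% of those computed from the true laws."""
        h, nh = self.cohorts()
        c = construct_range("x", h, nh)
        assert c.discriminative and c.direction == "right"
        true_h = LogLogisticFit(self.ALPHA_H, self.SHAPE, 0.0, 0)
        true_nh = LogLogisticFit(self.ALPHA_NH, self.SHAPE, 0.0, 0)
        true_thr = equal_density_threshold(true_h, true_nh)
        true_lo, true_hi = central_interval(true_h, 0.90)
        assert c.row.healthy[0] == pytest.approx(true_lo, rel=0.10)
        assert c.row.healthy[1] == pytest.approx(true_thr, rel=0.10)
        assert c.row.abnormal_bound == pytest.approx(true_hi, rel=0.10)

    def test_youden_closely_coincides_with_equal_density(self):
        h, nh = self.cohorts()
        c = construct_range("x", h, nh)
        assert c.youden_threshold == pytest.approx(c.equal_density, rel=0.15)

    def test_identical_cohorts_not_discriminative(self):
        x = loglogistic_samples(1.0, 4.0, 400, seed=33)
        y = loglogistic_samples(1.0, 4.0, 400, seed=34)
        table, constructions = build_range_table({"x": x}, {"x": y})
        assert len(table) == 0
        assert not constructions["x"].discriminative

    def test_healthy_median_classifies_normal(self):
        h, nh = self.cohorts()
        table, _ = build_range_table({"x": h}, {"x": nh})
        assert table.classify("x", self.ALPHA_H) == "normal"

    def test_no_false_discrimination_under_the_null(self):
        """Identical generating laws stay non-discriminative in >= 95% of seeds."""
        flagged = 0
        reps = 20
        for s in range(reps):
            a = loglogistic_samples(1.0, 4.0, 200, seed=100 + 2 * s)
            b = loglogistic_samples(1.0, 4.0, 200, seed=101 + 2 * s)
            c = construct_range("x", a, b)
            flagged += c.discriminative
        assert flagged <= 1  # at most 5% of 20 replicates
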