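import numpy as np
import pytest

import refband as rb
from refband.confidence import (
    ToleranceSpec,
    beta_exact_single_age,
    evaluate_confidence,
    local_coverage,
    mc_stderr,
    single_age_truth,
    simulate_sample,
)
from refband.designs import DesignSpec, realize_design


class TestMcStderr:
    def test_printed_values(self):
        assert mc_stderr(0.90, 10_000) == pytest.approx(0.003, abs=1e-12)
        assert mc_stderr(0.90, 40_000) == pytest.approx(0.0015, abs=1e-12)
        assert mc_stderr(1.0, 5000) == 0.0

    def test_domain(self):
        with pytest.raises(ValueError):
            mc_stderr(1.5, 100)
        with pytest.raises(ValueError):
            mc_stderr(0.5, 0)


class TestToleranceSpec:
    def test_windows(self):
        tol = ToleranceSpec(q=0.90, delta1=0.02, delta2=0.02)
        assert tol.lower_window == (pytest.approx(0.03), pytest.approx(0.07))
        assert tol.upper_window == (pytest.approx(0.93), pytest.approx(0.97))

    def test_window_must_stay_inside_unit_interval(self):
        with pytest.raises(ValueError):
            ToleranceSpec(q=0.90, delta1=0.06, delta2=0.02)  # lower bound < 0
        with pytest.raises(ValueError):
            ToleranceSpec(q=0.90, delta1=0.02, delta2=0.06)  # upper bound > 1


class TestSimulateSample:
    def test_reproducible(self, truth_II_gauss, grid_II):
        ages = realize_design(DesignSpec(n=100, a_star=1, b_star=1, grid=grid_II))
        s1 = simulate_sample(ages, truth_II_gauss, seed=4)
        s2 = simulate_sample(ages, truth_II_gauss, seed=4)
        assert np.array_equal(s1.values, s2.values)

    def test_location_scale_structure(self, grid_II):
        truth = rb.scenario_truth("II", "gaussian", gamma0=2.0)
        ages = np.full(100_000, 150.0)
        s = simulate_sample(ages, truth, seed=10)
        assert s.values.mean() == pytest.approx(truth.mu(150.0), abs=0.05)
        assert s.values.std() == pytest.approx(2.0, rel=0.02)

    def test_near_degenerate_scale(self, grid_II):
        truth = rb.scenario_truth("II", "gaussian", gamma0=1e-9)
        ages = np.full(100, 200.0)
        s = simulate_sample(ages, truth, seed=1)
        assert np.allclose(s.values, truth.mu(200.0), atol=1e-7)


class TestLocalCoverage:
    class _FixedBand:
        def __init__(self, lo, up):
            self.lo, self.up = lo, up

        def band_limits(self, t):
            t = np.asarray(t, float)
            return np.full_like(t, self.lo), np.full_like(t, self.up)

    def test_analytic_boundary_recovers_nominal_coverage(self, truth_II_gauss):
        from scipy.stats import norm

        t = 150.0
        mu, sig = truth_II_gauss.mu(t), truth_II_gauss.sigma(t)
        band = self._FixedBand(mu + norm.ppf(0.05) * sig, mu + norm.ppf(0.95) * sig)
        p_low, p_up = local_coverage(band, truth_II_gauss, np.array([t]))
        assert p_low[0] == pytest.approx(0.05, abs=1e-12)
        assert p_up[0] == pytest.approx(0.95, abs=1e-12)

    def test_monotone_in_boundary(self, truth_II_gauss):
        t = np.array([150.0])
        mu = truth_II_gauss.mu(150.0)
        lows = [
            local_coverage(self._FixedBand(mu + c, mu + 10), truth_II_gauss, t)[0][0]
            for c in (-2.0, -1.0, 0.0, 1.0)
        ]
        assert np.all(np.diff(lows) > 0)

    def test_far_upper_boundary_has_full_coverage(self, truth_II_gauss):
        band = self._FixedBand(0.0, 1e9)
        _, p_up = local_coverage(band, truth_II_gauss, np.array([150.0]))
        assert p_up[0] == pytest.approx(1.0)


class TestConfidenceProbability:
    def test_single_age_oracle_equivalence(self):
        """Monte Carlo beta_hat matches the Beta(r, n-r+1) window probability."""
        for fam in ("gaussian", "laplace"):
            truth = single_age_truth(rb.make_baseline(fam))
            for n, q, d in [(400, 0.90, 0.02), (900, 0.90, 0.03), (700, 0.95, 0.02)]:
                for side in ("lower", "upper"):
                    tol = ToleranceSpec(q=q, delta1=d, delta2=d, side=side)
                    est = rb.confidence_probability(
                        truth, np.zeros(n), tol, 3000, seed=17, use_true_curves=True
                    )
                    exact = beta_exact_single_age(n, tol)
                    se = max(mc_stderr(min(max(exact, 0.01), 0.99), 3000), 1e-4)
                    assert abs(est.beta_hat - exact) < 3 * se

    def test_two_sided_bounded_by_marginals(self, truth_II_gauss, grid_II):
        ages = realize_design(DesignSpec(n=800, a_star=1, b_star=1, grid=grid_II))
        ests = evaluate_confidence(truth_II_gauss, ages, ToleranceSpec(), 400, seed=3)
        assert ests["two_sided"].beta_hat <= min(
            ests["lower"].beta_hat, ests["upper"].beta_hat
        )
        # joint event frequency bounded age by age as well
        assert np.all(ests["two_sided"].per_age_freq <= ests["lower"].per_age_freq + 1e-12)

    def test_monotone_in_tolerance(self, truth_II_gauss, grid_II):
        ages = realize_design(DesignSpec(n=1000, a_star=1, b_star=1, grid=grid_II))
        betas = []
        for d in (0.012, 0.02, 0.035):
            tol = ToleranceSpec(q=0.90, delta1=d, delta2=d, side="lower")
            betas.append(
                rb.confidence_probability(truth_II_gauss, ages, tol, 500, seed=11).beta_hat
            )
        assert betas[0] <= betas[1] <= betas[2]

    def test_min_over_grid_nonincreasing_under_enlargement(self, truth_II_gauss, grid_II):
        ages = realize_design(DesignSpec(n=800, a_star=1, b_star=1, grid=grid_II))
        est = rb.confidence_probability(
            truth_II_gauss, ages, ToleranceSpec(side="lower"), 300, seed=2
        )
        subset = est.per_age_freq[::4]
        assert est.beta_hat <= np.min(subset) + 1e-12

    def test_symmetric_sides_agree(self, truth_II_gauss, grid_II):
        ages = realize_design(DesignSpec(n=2000, a_star=1, b_star=1, grid=grid_II))
        ests = evaluate_confidence(
            truth_II_gauss, ages, ToleranceSpec(), 1500, seed=29
        )
        lo, up = ests["lower"], ests["upper"]
        assert abs(lo.beta_hat - up.beta_hat) <= 3 * (lo.stderr + up.stderr)

    def test_estimate_metadata(self, truth_II_gauss, grid_II):
        ages = realize_design(DesignSpec(n=500, a_star=1, b_star=1, grid=grid_II))
        est = rb.confidence_probability(
            truth_II_gauss, ages, ToleranceSpec(side="lower"), 200, seed=0
        )
        assert est.beta_hat == pytest.approx(np.min(est.per_age_freq))
        assert est.stderr == pytest.approx(mc_stderr(est.beta_hat, 200))
        assert 0 <= est.n_failed <= 200
        assert np.all((est.per_age_freq >= 0) & (est.per_age_freq <= 1))

    def test_reproducible_under_seed(self, truth_II_gauss, grid_II):
        ages = realize_design(DesignSpec(n=400, a_star=1, b_star=1, grid=grid_II))
        a = rb.confidence_probability(truth_II_gauss, ages, ToleranceSpec(), 300, seed=8)
        b = rb.confidence_probability(truth_II_gauss, ages, ToleranceSpec(), 300, seed=8)
        assert np.array_equal(a.per_age_freq, b.per_age_freq)

    def test_design_off_grid_rejected(self, truth_II_gauss):
        with pytest.raises(ValueError, match="grid"):
            rb.confidence_probability(
                truth_II_gauss, np.array([150.5] * 300), ToleranceSpec(), 10, seed=0
            )
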