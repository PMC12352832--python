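import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import refband as rb
from refband import mean_models as mm
from refband.band import (
    MomentSummary,
    ReferenceBandModel,
    Sample,
    empirical_band_counts,
    estimate_band,
    parametric_limits,
    reference_ranks,
)
from refband.designs import DesignSpec, realize_design


class TestReferenceRanks:
    @pytest.mark.parametrize(
        "n,q,expected",
        [
            (2110, 0.90, (106, 2005)),
            (100, 0.90, (6, 96)),
            (20, 0.90, (2, 20)),
            (10_000, 0.90, (501, 9501)),
            (2110, 0.95, (53, 2058)),
        ],
    )
    def test_printed_rank_rule(self, n, q, expected):
        assert reference_ranks(n, q) == expected

    def test_integer_boundary_steps_up(self):
        # smallest integer *exceeding* 5 is 6, not 5
        assert reference_ranks(100, 0.90)[0] == 6

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(n=st.integers(10, 50_000), q=st.sampled_from([0.5, 0.8, 0.9, 0.95, 0.99]))
    def test_rank_rule_properties(self, n, q):
        r_l, r_u = reference_ranks(n, q)
        assert r_l > n * (1 - q) / 2 - 1e-9
        assert r_l - 1 <= n * (1 - q) / 2 + 1e-9
        assert r_u > n * (1 + q) / 2 - 1e-9
        assert 1 <= r_l < r_u <= n

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            reference_ranks(0, 0.9)
        with pytest.raises(ValueError):
            reference_ranks(100, 1.0)


class TestBandEstimation:
    def test_order_statistic_count_identity(self, truth_II_gauss, grid_II):
        ages = realize_design(DesignSpec(n=10_000, a_star=1, b_star=1, grid=grid_II))
        sample = rb.simulate_sample(ages, truth_II_gauss, seed=77)
        res = estimate_band(sample, "II", q=0.90)
        below, above = res.empirical_counts()
        r_l, r_u = reference_ranks(10_000, 0.90)
        assert (below, above) == (r_l - 1, 10_000 - r_u)  # (500, 499)
        assert below + above + (10_000 - below - above) == 10_000

    def test_interior_proportion_near_q(self, simulated_sample_II):
        res = estimate_band(simulated_sample_II, "II", q=0.90)
        below, above = res.empirical_counts()
        interior = simulated_sample_II.n - below - above
        assert interior / simulated_sample_II.n == pytest.approx(0.90, abs=0.01)

    def test_band_coefficients_signs(self, simulated_sample_II):
        res = estimate_band(simulated_sample_II, "II", q=0.90)
        assert res.k_l < 0 < res.k_u

    def test_boundaries_order_and_width(self, simulated_sample_II, grid_II):
        res = estimate_band(simulated_sample_II, "II", q=0.90)
        lo, up = res.band_limits(grid_II.ages)
        mu = res.mean_fit(grid_II.ages)
        assert np.all(lo < mu) and np.all(mu < up)

    def test_constant_dispersion_gives_constant_width(self, grid_II, truth_II_gauss):
        ages = realize_design(DesignSpec(n=3000, a_star=1, b_star=1, grid=grid_II))
        sample = rb.simulate_sample(ages, truth_II_gauss, seed=5)
        res = estimate_band(sample, "II")
        # force a flat dispersion line and check the width is flat too
        res.disp_fit = mm.DispersionParams(1.3, 0.0, grid_II.t_lo, grid_II.t_hi)
        lo, up = res.band_limits(grid_II.ages)
        assert np.allclose(up - lo, (up - lo)[0])

    def test_increasing_dispersion_widens_band(self, grid_II):
        truth = rb.scenario_truth("II", "gaussian", gamma1=0.786)
        ages = realize_design(DesignSpec(n=4000, a_star=1, b_star=1, grid=grid_II))
        sample = rb.simulate_sample(ages, truth, seed=6)
        res = estimate_band(sample, "II")
        lo, up = res.band_limits(grid_II.ages)
        width = up - lo
        assert width[-1] > width[0]
        assert np.all(np.diff(width) > -1e-9)

    def test_scale_equivariance_quartic(self, simulated_sample_II):
        lam = 3.7
        res1 = estimate_band(simulated_sample_II, "II")
        res2 = estimate_band(
            Sample(simulated_sample_II.ages, lam * simulated_sample_II.values), "II"
        )
        t = np.linspace(77, 280, 23)
        for lim1, lim2 in zip(res1.band_limits(t), res2.band_limits(t)):
            assert np.allclose(lam * lim1, lim2, rtol=1e-8)

    def test_scale_equivariance_growth(self, truth_I_gauss, grid_I):
        lam = 2.5
        ages = realize_design(DesignSpec(n=1000, a_star=1, b_star=1, grid=grid_I))
        sample = rb.simulate_sample(ages, truth_I_gauss, seed=9)
        init = truth_I_gauss.mean
        init_scaled = mm.GrowthCurveParams(
            init.a, init.b, lam * init.c, init.d, init.t_lo, init.t_hi
        )
        res1 = estimate_band(sample, "I", growth_init=init)
        res2 = estimate_band(
            Sample(sample.ages, lam * sample.values), "I", growth_init=init_scaled
        )
        t = np.linspace(10, 41, 23)
        for lim1, lim2 in zip(res1.band_limits(t), res2.band_limits(t)):
            assert np.allclose(lam * lim1, lim2, rtol=1e-6)

    def test_invariance_under_dispersion_rescaling(self, simulated_sample_II, grid_II):
        """The proportionality constant of the scale estimate cancels."""
        res = estimate_band(simulated_sample_II, "II")
        c = 4.2
        disp_scaled = mm.DispersionParams(
            c * res.disp_fit.gamma0, c * res.disp_fit.gamma1, grid_II.t_lo, grid_II.t_hi
        )
        s = simulated_sample_II
        resid = s.values - res.mean_fit(s.ages)
        scaled = resid / mm.sigma_eval(disp_scaled, s.ages)
        order = np.sort(scaled)
        k_l2, k_u2 = order[res.r_l - 1], order[res.r_u - 1]
        t = grid_II.ages
        lo2 = res.mean_fit(t) + k_l2 * mm.sigma_eval(disp_scaled, t)
        up2 = res.mean_fit(t) + k_u2 * mm.sigma_eval(disp_scaled, t)
        lo1, up1 = res.band_limits(t)
        assert np.allclose(lo1, lo2, rtol=1e-10)
        assert np.allclose(up1, up2, rtol=1e-10)

    def test_symmetric_baseline_coefficients_cancel(self, truth_II_gauss, grid_II):
        ages = realize_design(DesignSpec(n=20_000, a_star=1, b_star=1, grid=grid_II))
        sample = rb.simulate_sample(ages, truth_II_gauss, seed=123)
        res = estimate_band(sample, "II")
        assert abs(res.k_l + res.k_u) < 0.1  # symmetric law, large n


class TestModelInterface:
    def test_from_dataframe(self, simulated_sample_II):
        import pandas as pd

        frame = pd.DataFrame(
            {"age": simulated_sample_II.ages, "value": simulated_sample_II.values}
        )
        res = ReferenceBandModel.from_dataframe(frame, mean_model="quartic").fit()
        assert res.n == simulated_sample_II.n

    def test_summary_and_frame(self, simulated_sample_II):
        res = estimate_band(simulated_sample_II, "II")
        text = res.summary()
        assert "target coverage" in text and "k_l" in text
        tab = res.as_frame()
        assert list(tab.columns) == ["age", "lower", "upper", "mu_hat", "sigma_hat"]
        assert np.all(tab["lower"] < tab["upper"])

    def test_counts_on_foreign_sample(self, simulated_sample_II, truth_II_gauss):
        res = estimate_band(simulated_sample_II, "II")
        other = rb.simulate_sample(simulated_sample_II.ages, truth_II_gauss, seed=999)
        below, above = empirical_band_counts(res, other)
        n = other.n
        # roughly 5% in each tail for an independent sample
        assert 0.02 < below / n < 0.08
        assert 0.02 < above / n < 0.08


class TestParametricLimits:
    def test_printed_normal_quantiles(self):
        lo, up = parametric_limits(MomentSummary(0.0, 1.0), 0.95)
        assert up == pytest.approx(1.95996, abs=1e-5)
        assert lo == pytest.approx(-1.95996, abs=1e-5)
        lo, up = parametric_limits(MomentSummary(0.0, 1.0), 0.90)
        assert up == pytest.approx(1.64485, abs=1e-5)

    def test_degenerate_sd(self):
        lo, up = parametric_limits(MomentSummary(3.0, 0.0), 0.9)
        assert lo == up == 3.0
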