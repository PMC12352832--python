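"""Distribution-free age-dependent reference bands.

Given a sample of pairs ``(t_i, Y_i)`` the band with two-sided target
coverage ``q`` is built in four steps:

1. fit a mean curve ``mu_hat(t)`` by ordinary least squares (beta-cdf growth
   model or quartic polynomial);
2. fit a line to the absolute residuals to obtain the dispersion estimate
   ``sigma_hat(t)``;
3. take the order statistics of ranks ``r_n((1-q)/2)`` and ``r_n((1+q)/2)``
   of the scaled residuals ``(Y_i - mu_hat(t_i)) / sigma_hat(t_i)``, where
   ``r_n(p)`` is the smallest integer exceeding ``n * p`` — these are the
   band coefficients ``k_l < 0 < k_u``;
4. the band boundaries are ``L_n(t) = mu_hat(t) + k_l * sigma_hat(t)`` and
   ``U_n(t) = mu_hat(t) + k_u * sigma_hat(t)``.

By construction the band contains (almost) exactly a proportion ``q`` of the
data points, with equal tails, at every sample size — no distributional
assumption on the standardized residuals is needed beyond continuity.

The module follows the Model/Results idiom: build a
:class:`ReferenceBandModel` from data and call :meth:`~ReferenceBandModel.fit`
to obtain a :class:`ReferenceBandResults` carrying the fitted curves, the
band coefficients and diagnostic counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .designs import AgeGrid, make_grid
from . import mean_models as mm

__all__ = [
    "Sample",
    "MomentSummary",
    "reference_ranks",
    "ReferenceBandModel",
    "ReferenceBandResults",
    "estimate_band",
    "band_limits",
    "empirical_band_counts",
    "parametric_limits",
]


@dataclass(frozen=True)
class Sample:
    """Observed (age, marker value) pairs."""

    ages: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if ages.shape != values.shape or ages.ndim != 1 or len(ages) < 1:
            raise ValueError("ages and values must be equal-length 1-d arrays")
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return len(self.ages)


@dataclass(frozen=True)
class MomentSummary:
    """Mean and standard deviation of an age-independent marker sample."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("standard deviation must be non-negative")


def reference_ranks(n: int, q: float) -> tuple[int, int]:
    """Ranks of the order statistics anchoring a coverage-``q`` band.

    ``r_l`` is the smallest integer exceeding ``n(1-q)/2`` and ``r_u`` the
    smallest integer exceeding ``n(1+q)/2``; at integer boundaries the rule
    steps up (``n=100, q=0.90`` gives ranks ``(6, 96)``, not ``(5, 95)``).

    Raises
    ------
    ValueError
        If ``n`` is too small for the requested coverage (``r_u > n``).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < q < 1:
        raise ValueError("coverage q must lie strictly inside (0, 1)")
    def smallest_exceeding(x: float) -> int:
        # guard against float noise at integer boundaries (e.g. 100 * 0.05)
        nearest = round(x)
        if abs(x - nearest) < 1e-9 * max(1.0, abs(x)):
            return int(nearest) + 1
        return math.floor(x) + 1

    r_l = smallest_exceeding(n * (1 - q) / 2)
    r_u = smallest_exceeding(n * (1 + q) / 2)
    if r_u > n:
        raise ValueError(
            f"sample size n={n} too small for coverage q={q} (upper rank {r_u} > n)"
        )
    return r_l, r_u


class ReferenceBandModel:
    """Distribution-free reference band for an age-dependent marker.

    Parameters
    ----------
    ages, values : array-like
        The sample of (age, marker) pairs.
    mean_model : {"growth", "quartic"}
        Family of the mean curve: the beta-cdf growth model (iterative fit)
        or a quartic polynomial (closed-form OLS).
    q : float
        Two-sided target coverage of the band (default 0.90).
    grid : AgeGrid or {"I", "II"}, optional
        Working age grid; defaults to the span of the observed ages on a
        200-point lattice.  Used for positivity checks of the dispersion
        line and as the default evaluation set.
    growth_init : GrowthCurveParams, optional
        Starting values for the growth-model fit; a data-driven heuristic is
        used when omitted.
    """

    def __init__(self, ages, values, *, mean_model: str = "growth", q: float = 0.90,
                 grid: AgeGrid | str | None = None, growth_init=None):
        self.sample = Sample(np.asarray(ages, float), np.asarray(values, float))
        if mean_model not in ("growth", "quartic"):
            raise ValueError("mean_model must be 'growth' or 'quartic'")
        self.mean_model = mean_model
        if not 0 < q < 1:
            raise ValueError("q must lie in (0, 1)")
        self.q = float(q)
        if isinstance(grid, str):
            grid = make_grid(grid)
        if grid is None:
            lo, hi = float(self.sample.ages.min()), float(self.sample.ages.max())
            grid = AgeGrid(np.linspace(lo, hi, 200))
        self.grid = grid
        self.growth_init = growth_init

    @classmethod
    def from_dataframe(cls, frame, *, age_col: str = "age", value_col: str = "value",
                       **kwargs) -> "ReferenceBandModel":
        """Build the model from a DataFrame with age and value columns."""
        return cls(frame[age_col].to_numpy(), frame[value_col].to_numpy(), **kwargs)

    def fit(self) -> "ReferenceBandResults":
        """Run the four estimation steps and return the fitted band."""
        s = self.sample
        r_l, r_u = reference_ranks(s.n, self.q)
        t_lo, t_hi = self.grid.t_lo, self.grid.t_hi
        if self.mean_model == "growth":
            init = self.growth_init or mm.default_growth_init(s.ages, s.values, t_lo, t_hi)
            mean_fit = mm.fit_growth(s.ages, s.values, init)
        else:
            mean_fit = mm.fit_poly(s.ages, s.values)
        mu_hat = mean_fit(s.ages)
        resid = s.values - mu_hat
        disp_fit = mm.fit_dispersion(
            s.ages, np.abs(resid), t_lo, t_hi, check_grid=self.grid.ages
        )
        scaled = resid / mm.sigma_eval(disp_fit, s.ages)
        order = np.sort(scaled)
        k_l = float(order[r_l - 1])
        k_u = float(order[r_u - 1])
        return ReferenceBandResults(self, mean_fit, disp_fit, k_l, k_u, r_l, r_u, scaled)


class ReferenceBandResults:
    """Fitted reference band: curves, coefficients and diagnostics.

    Attributes
    ----------
    mean_fit : GrowthCurveParams or PolyCurveParams
        Fitted mean curve (callable at ages).
    disp_fit : DispersionParams
        Fitted dispersion line (callable at ages).
    k_l, k_u : float
        Order-statistic band coefficients (``k_l < k_u``; opposite signs for
        centered residuals).
    """

    def __init__(self, model, mean_fit, disp_fit, k_l, k_u, r_l, r_u, scaled_residuals):
        self.model = model
        self.mean_fit = mean_fit
        self.disp_fit = disp_fit
        self.k_l = k_l
        self.k_u = k_u
        self.r_l = r_l
        self.r_u = r_u
        self.scaled_residuals = np.asarray(scaled_residuals)
        self.q = model.q
        self.n = model.sample.n

    def band_limits(self, t):
        """Lower and upper band boundaries ``(L(t), U(t))`` at ages ``t``."""
        mu = self.mean_fit(t)
        sig = mm.sigma_eval(self.disp_fit, t)
        return mu + self.k_l * sig, mu + self.k_u * sig

    def empirical_counts(self) -> tuple[int, int]:
        """Number of sample points strictly below / above the band.

        With continuous data these equal ``r_l - 1`` and ``n - r_u`` almost
        surely; ties (possible in rounded user data) are broken toward the
        band interior by the strict inequalities.
        """
        s = self.model.sample
        lo, up = self.band_limits(s.ages)
        return int(np.sum(s.values < lo)), int(np.sum(s.values > up))

    def as_frame(self, t=None):
        """Tabulate age, L, U, mu_hat, sigma_hat on ``t`` (default: grid)."""
        import pandas as pd

        t = self.model.grid.ages if t is None else np.asarray(t, float)
        lo, up = self.band_limits(t)
        return pd.DataFrame(
            {
                "age": t,
                "lower": lo,
                "upper": up,
                "mu_hat": self.mean_fit(t),
                "sigma_hat": mm.sigma_eval(self.disp_fit, t),
            }
        )

    def summary(self) -> str:
        """Plain-text summary of the fitted band."""
        below, above = self.empirical_counts()
        lines = [
            "Distribution-free reference band",
            "=" * 44,
            f"observations            {self.n}",
            f"target coverage q       {self.q:.4f}",
            f"mean model              {self.model.mean_model}",
            f"ranks (r_l, r_u)        ({self.r_l}, {self.r_u})",
            f"band coefficients       k_l = {self.k_l:+.5f}, k_u = {self.k_u:+.5f}",
            f"dispersion line         gamma0 = {self.disp_fit.gamma0:.5f}, "
            f"gamma1 = {self.disp_fit.gamma1:.5f}",
            f"points below | above    {below} | {above}"
            f"   (expected {self.r_l - 1} | {self.n - self.r_u})",
        ]
        if isinstance(self.mean_fit, mm.GrowthCurveParams):
            p = self.mean_fit
            lines.insert(
                6,
                f"growth params           a = {p.a:.4f}, b = {p.b:.4f}, "
                f"c = {p.c:.4f}, d = {p.d:.4f}",
            )
        else:
            c = ", ".join(f"{v:.6g}" for v in self.mean_fit.coeffs)
            lines.insert(6, f"quartic coefficients    [{c}]")
        return "\n".join(lines)

    def plot(self, ax=None, *, show_data: bool = True):
        """Plot data cloud with the fitted band (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.model.grid.ages
        lo, up = self.band_limits(t)
        if show_data:
            s = self.model.sample
            ax.plot(s.ages, s.values, ".", ms=2, alpha=0.3, color="grey")
        ax.plot(t, self.mean_fit(t), "-", color="C0", label="mean curve")
        ax.plot(t, lo, "-", color="C3", label=f"{self.q:.0%} band")
        ax.plot(t, up, "-", color="C3")
        ax.set_xlabel(f"age [{self.model.grid.units}]")
        ax.set_ylabel("marker value")
        ax.legend()
        return ax


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def estimate_band(sample: Sample, scenario: str, q: float = 0.90,
                  growth_init=None) -> ReferenceBandResults:
    """Fit the reference band using a built-in scenario grid.

    ``scenario="I"`` selects the growth-model mean curve on the weekly grid,
    ``scenario="II"`` the quartic on the daily grid.
    """
    mean_model = "growth" if scenario == "I" else "quartic"
    model = ReferenceBandModel(
        sample.ages, sample.values, mean_model=mean_model, q=q,
        grid=make_grid(scenario), growth_init=growth_init,
    )
    return model.fit()


def band_limits(band: ReferenceBandResults, t):
    """Functional alias for :meth:`ReferenceBandResults.band_limits`."""
    return band.band_limits(t)


def empirical_band_counts(band: ReferenceBandResults, sample: Sample | None = None):
    """Counts of points strictly below / above the fitted band."""
    if sample is not None and sample is not band.model.sample:
        lo, up = band.band_limits(sample.ages)
        return int(np.sum(sample.values < lo)), int(np.sum(sample.values > up))
    return band.empirical_counts()


def parametric_limits(ms: MomentSummary, q: float) -> tuple[float, float]:
    """Gaussian-theory reference limits ``mean -/+ z_{(1+q)/2} * sd``."""
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    z = stats.norm.ppf((1 + q) / 2)
    return ms.mean - z * ms.sd, ms.mean + z * ms.sd
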