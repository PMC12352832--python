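"""Monte Carlo evaluation of the confidence-probability precision criterion.

The precision of an estimated reference band is judged through the coverage
its boundaries attain in the *true* conditional distribution: at age ``t``
the lower boundary cuts off probability ``F((L_n(t) - mu(t)) / sigma(t))``,
which should stay within small tolerances ``(delta1, delta2)`` of its target
``(1-q)/2`` (analogously ``(1+q)/2`` for the upper boundary).  The
confidence probability of a design is the probability of that event at the
*least favourable* age of the measurement grid:

    beta_L(n)     = min_t P[ (1-q)/2 - d1 < F((L_n(t)-mu(t))/sigma(t)) < (1-q)/2 + d2 ]
    beta_U(n)     = min_t P[ (1+q)/2 - d1 < F((U_n(t)-mu(t))/sigma(t)) < (1+q)/2 + d2 ]
    beta_{L,U}(n) = min_t P[ both windows hold jointly at the same t ]

Except in the degenerate single-age case these probabilities admit no exact
representation, so they are estimated by simulation: per-age event
frequencies over ``n_rep`` replicated band estimations, then the minimum
over the grid.  Replicates whose mean fit fails to converge or whose
dispersion line goes non-positive on the grid count as failures of the
event (conservative) and are tallied separately.

All replicate data of one evaluation come from a single counter-based
(Philox) stream keyed on the master seed and the sample size, so the three
criteria (and both one-sided variants) share replicates, and the whole
experiment is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from . import mean_models as mm
from .band import Sample, reference_ranks
from .designs import AgeGrid
from .distributions import BaselineDistribution

__all__ = [
    "ScenarioTruth",
    "ToleranceSpec",
    "ConfidenceEstimate",
    "simulate_sample",
    "local_coverage",
    "confidence_probability",
    "evaluate_confidence",
    "mc_stderr",
    "beta_exact_single_age",
]

SIDES = ("lower", "upper", "two_sided")


@dataclass(frozen=True)
class ScenarioTruth:
    """The data-generating configuration: true curves, baseline law, grid."""

    mean: object  # callable mean curve (GrowthCurveParams / PolyCurveParams / scalar fn)
    disp: mm.DispersionParams
    baseline: BaselineDistribution
    grid: AgeGrid
    mean_model: str = "growth"  # "growth" | "quartic" | "constant"

    def mu(self, t):
        return self.mean(t)

    def sigma(self, t):
        return self.disp(t)


@dataclass(frozen=True)
class ToleranceSpec:
    """Target coverage, tolerances and the side of interest."""

    q: float = 0.90
    delta1: float = 0.02
    delta2: float = 0.02
    side: str = "lower"

    def __post_init__(self) -> None:
        if not 0 < self.q < 1:
            raise ValueError("q must lie in (0, 1)")
        if not (self.delta1 > 0 and self.delta2 > 0):
            raise ValueError("tolerances must be positive")
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}")
        lo, hi = self.lower_window
        if not 0 < lo < hi < 1:
            raise ValueError("lower tolerance window must lie inside (0, 1)")
        lo, hi = self.upper_window
        if not 0 < lo < hi < 1:
            raise ValueError("upper tolerance window must lie inside (0, 1)")

    @property
    def lower_window(self) -> tuple[float, float]:
        c = (1 - self.q) / 2
        return c - self.delta1, c + self.delta2

    @property
    def upper_window(self) -> tuple[float, float]:
        c = (1 + self.q) / 2
        return c - self.delta1, c + self.delta2


@dataclass
class ConfidenceEstimate:
    """Simulated confidence probability for one side at one sample size."""

    side: str
    n: int
    n_rep: int
    ages: np.ndarray = field(repr=False)
    per_age_freq: np.ndarray = field(repr=False)
    beta_hat: float = 0.0
    argmin_age: float = np.nan
    stderr: float = np.nan
    n_failed: int = 0

    @classmethod
    def from_counts(cls, side, n, n_rep, grid_ages, counts, n_failed):
        freq = counts / n_rep
        i = int(np.argmin(freq))
        beta = float(freq[i])
        return cls(
            side=side,
            n=n,
            n_rep=n_rep,
            ages=np.asarray(grid_ages),
            per_age_freq=freq,
            beta_hat=beta,
            argmin_age=float(grid_ages[i]),
            stderr=mc_stderr(beta, n_rep),
            n_failed=int(n_failed),
        )


def mc_stderr(beta_hat: float, n_rep: int) -> float:
    """Binomial standard error ``sqrt(beta (1 - beta) / n_rep)``."""
    if not 0 <= beta_hat <= 1:
        raise ValueError("beta_hat must lie in [0, 1]")
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    return float(np.sqrt(beta_hat * (1.0 - beta_hat) / n_rep))


def simulate_sample(ages: np.ndarray, truth: ScenarioTruth, seed) -> Sample:
    """Draw one sample ``Y_i = mu(t_i) + sigma(t_i) eps_i`` on the design."""
    ages = np.asarray(ages, dtype=float)
    rng = np.random.default_rng(seed)
    eps = truth.baseline.sample(rng, len(ages))
    return Sample(ages, np.asarray(truth.mu(ages)) + np.asarray(truth.sigma(ages)) * eps)


def local_coverage(band, truth: ScenarioTruth, t) -> tuple[float, float]:
    """True probability content cut off by the fitted boundaries at age t."""
    lo, up = band.band_limits(t)
    mu = np.asarray(truth.mu(t), dtype=float)
    sig = np.asarray(truth.sigma(t), dtype=float)
    return truth.baseline.cdf((lo - mu) / sig), truth.baseline.cdf((up - mu) / sig)


# ---------------------------------------------------------------------------
# Monte Carlo engines
# ---------------------------------------------------------------------------

def _replication_rng(seed, n: int) -> np.random.Generator:
    """Counter-based stream shared by all criteria at one (seed, n) cell."""
    return np.random.Generator(np.random.Philox(np.random.SeedSequence([int(seed), int(n)])))


class _Accumulator:
    def __init__(self, k: int):
        self.low = np.zeros(k, dtype=np.int64)
        self.up = np.zeros(k, dtype=np.int64)
        self.joint = np.zeros(k, dtype=np.int64)
        self.failed = 0

    def add_events(self, ev_low, ev_up):
        # ev_*: (reps, K) boolean
        self.low += ev_low.sum(axis=0)
        self.up += ev_up.sum(axis=0)
        self.joint += (ev_low & ev_up).sum(axis=0)


def _window_events(p_low, p_up, tol: ToleranceSpec):
    lo1, hi1 = tol.lower_window
    lo2, hi2 = tol.upper_window
    ev_low = (p_low > lo1) & (p_low < hi1)
    ev_up = (p_up > lo2) & (p_up < hi2)
    return ev_low, ev_up


def _engine_order_statistics(truth, ages, tol, n_rep, rng, acc, r_l, r_u, grid_idx):
    """Oracle mode: true curves known, band anchored at raw order statistics."""
    n = len(ages)
    k = len(truth.grid)
    chunk = max(1, min(n_rep, int(4_000_000 // max(n, 1))))
    done = 0
    while done < n_rep:
        m = min(chunk, n_rep - done)
        eps = truth.baseline.sample(rng, (m, n))
        part = np.partition(eps, (r_l - 1, r_u - 1), axis=1)
        k_l = part[:, r_l - 1]
        k_u = part[:, r_u - 1]
        # with true curves, (L(t)-mu(t))/sigma(t) == k_l at every age
        p_low = np.broadcast_to(truth.baseline.cdf(k_l)[:, None], (m, k))
        p_up = np.broadcast_to(truth.baseline.cdf(k_u)[:, None], (m, k))
        acc.add_events(*_window_events(p_low, p_up, tol))
        done += m


def _engine_quartic(truth, ages, tol, n_rep, rng, acc, r_l, r_u, grid_idx):
    """Closed-form OLS scenario, vectorized across replicates."""
    grid = truth.grid
    n = len(ages)
    t_g = grid.ages
    mu_g = np.asarray(truth.mu(t_g), dtype=float)
    sig_g = np.asarray(truth.sigma(t_g), dtype=float)
    s_g = grid.scaled(t_g)
    s_i = grid.scaled(ages)
    mu_i = mu_g[grid_idx]
    sig_i = sig_g[grid_idx]

    # orthogonalized quartic design on a centered/scaled age axis
    mid = 0.5 * (grid.t_lo + grid.t_hi)
    half = 0.5 * (grid.t_hi - grid.t_lo)
    u_i = (ages - mid) / half
    u_g = (t_g - mid) / half
    X = np.vander(u_i, 5, increasing=True)
    Q, R = np.linalg.qr(X)
    Xg = np.vander(u_g, 5, increasing=True)
    W = np.linalg.solve(R.T, Xg.T).T  # K x 5, mu_hat_grid = Z @ W.T

    D = np.column_stack([np.ones(n), s_i])
    Qd, Rd = np.linalg.qr(D)
    Gd = np.linalg.inv(Rd)

    chunk = max(1, min(n_rep, int(2_000_000 // max(n, 1))))
    done = 0
    while done < n_rep:
        m = min(chunk, n_rep - done)
        eps = truth.baseline.sample(rng, (m, n))
        y = mu_i + sig_i * eps
        z = y @ Q  # m x 5
        resid = y - z @ Q.T
        gam = (np.abs(resid) @ Qd) @ Gd.T  # m x 2
        sig_hat_g = gam[:, :1] + gam[:, 1:] * s_g[None, :]
        ok = sig_hat_g.min(axis=1) > 0
        sig_hat_i = gam[:, :1] + gam[:, 1:] * s_i[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            scaled = resid / sig_hat_i
        scaled[~ok] = 0.0  # placeholder rows, masked below
        part = np.partition(scaled, (r_l - 1, r_u - 1), axis=1)
        k_l = part[:, r_l - 1 : r_l]
        k_u = part[:, r_u - 1 : r_u]
        mu_hat_g = z @ W.T
        p_low = truth.baseline.cdf((mu_hat_g + k_l * sig_hat_g - mu_g) / sig_g)
        p_up = truth.baseline.cdf((mu_hat_g + k_u * sig_hat_g - mu_g) / sig_g)
        ev_low, ev_up = _window_events(p_low, p_up, tol)
        ev_low[~ok] = False
        ev_up[~ok] = False
        acc.add_events(ev_low, ev_up)
        acc.failed += int((~ok).sum())
        done += m


def _engine_growth(truth, ages, tol, n_rep, rng, acc, r_l, r_u, grid_idx):
    """Iterative growth-model scenario, replicate-by-replicate."""
    from scipy.special import betainc

    grid = truth.grid
    n = len(ages)
    t_g = grid.ages
    mu_g = np.asarray(truth.mu(t_g), dtype=float)
    sig_g = np.asarray(truth.sigma(t_g), dtype=float)
    s_g = grid.scaled(t_g)
    s_i = grid.scaled(ages)
    mu_i = mu_g[grid_idx]
    sig_i = sig_g[grid_idx]

    # aggregation over distinct observed ages (subset of the grid)
    obs_g, inv, cnt = np.unique(grid_idx, return_inverse=True, return_counts=True)
    x_obs = np.clip(s_g[obs_g], 0.0, 1.0)
    w_obs = cnt.astype(float)
    x_full = np.clip(s_g, 0.0, 1.0)
    ab0 = np.array([truth.mean.a, truth.mean.b])  # truth-initialized fits

    # precomputed 2x2 solve for the dispersion line
    sm = np.array([[n, s_i.sum()], [s_i.sum(), (s_i * s_i).sum()]])
    sm_inv = np.linalg.inv(sm)

    lo1, hi1 = tol.lower_window
    lo2, hi2 = tol.upper_window

    for _ in range(n_rep):
        eps = truth.baseline.sample(rng, n)
        y = mu_i + sig_i * eps
        ybar = np.bincount(inv, weights=y, minlength=len(obs_g)) / cnt
        try:
            res = optimize.least_squares(
                lambda ab: mm._growth_profile(ab, x_obs, ybar, w_obs)[0],
                x0=ab0,
                bounds=([1e-8, 1e-8], [np.inf, np.inf]),
                xtol=1e-10,
                ftol=1e-10,
                gtol=1e-10,
                max_nfev=600,
            )
            _, (b0, b1) = mm._growth_profile(res.x, x_obs, ybar, w_obs)
            if res.status <= 0 or not (np.isfinite(b0) and np.isfinite(b1)):
                raise mm.FitError("growth fit did not converge")
            a_hat, b_hat = res.x
            mu_hat_full = b0 + b1 * betainc(a_hat, b_hat, x_full)
            resid = y - mu_hat_full[grid_idx]
            av = np.abs(resid)
            g0, g1 = sm_inv @ np.array([av.sum(), s_i @ av])
            sig_hat_full = g0 + g1 * s_g
            if sig_hat_full.min() <= 0:
                raise mm.FitError("dispersion line non-positive on grid")
            scaled = resid / (g0 + g1 * s_i)
            part = np.partition(scaled, (r_l - 1, r_u - 1))
            k_l, k_u = part[r_l - 1], part[r_u - 1]
            p_low = truth.baseline.cdf((mu_hat_full + k_l * sig_hat_full - mu_g) / sig_g)
            p_up = truth.baseline.cdf((mu_hat_full + k_u * sig_hat_full - mu_g) / sig_g)
        except mm.FitError:
            acc.failed += 1
            continue
        ev_low = (p_low > lo1) & (p_low < hi1)
        ev_up = (p_up > lo2) & (p_up < hi2)
        acc.low += ev_low
        acc.up += ev_up
        acc.joint += ev_low & ev_up


def evaluate_confidence(
    truth: ScenarioTruth,
    ages: np.ndarray,
    tol: ToleranceSpec,
    n_rep: int,
    seed,
    *,
    use_true_curves: bool = False,
) -> dict[str, ConfidenceEstimate]:
    """Estimate all three confidence probabilities on shared replicates.

    Parameters
    ----------
    ages : array-like
        The realized design (ages on the truth's grid), fixed across
        replications.
    n_rep : int
        Number of Monte Carlo replications.
    use_true_curves : bool
        Skip the estimation steps and anchor the band at the raw order
        statistics of the standardized data (the degenerate oracle mode used
        for validation; exact closed forms exist only in the single-age case).

    Returns
    -------
    dict mapping side -> :class:`ConfidenceEstimate`.
    """
    ages = np.sort(np.asarray(ages, dtype=float))
    n = len(ages)
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    r_l, r_u = reference_ranks(n, tol.q)
    grid_idx = np.searchsorted(truth.grid.ages, ages)
    grid_idx = np.clip(grid_idx, 0, len(truth.grid) - 1)
    if not np.allclose(truth.grid.ages[grid_idx], ages, atol=1e-9):
        raise ValueError("design ages must lie on the truth's age grid")

    rng = _replication_rng(seed, n)
    acc = _Accumulator(len(truth.grid))
    if use_true_curves or truth.mean_model == "constant":
        engine = _engine_order_statistics
    elif truth.mean_model == "quartic":
        engine = _engine_quartic
    else:
        engine = _engine_growth
    engine(truth, ages, tol, n_rep, rng, acc, r_l, r_u, grid_idx)

    g = truth.grid.ages
    return {
        "lower": ConfidenceEstimate.from_counts("lower", n, n_rep, g, acc.low, acc.failed),
        "upper": ConfidenceEstimate.from_counts("upper", n, n_rep, g, acc.up, acc.failed),
        "two_sided": ConfidenceEstimate.from_counts(
            "two_sided", n, n_rep, g, acc.joint, acc.failed
        ),
    }


def confidence_probability(
    truth: ScenarioTruth,
    ages: np.ndarray,
    tol: ToleranceSpec,
    n_rep: int,
    seed,
    *,
    use_true_curves: bool = False,
) -> ConfidenceEstimate:
    """Simulated confidence probability for the side requested in ``tol``."""
    return evaluate_confidence(
        truth, ages, tol, n_rep, seed, use_true_curves=use_true_curves
    )[tol.side]


def single_age_truth(
    baseline: BaselineDistribution, *, mu: float = 0.0, sigma: float = 1.0, age: float = 0.0
) -> ScenarioTruth:
    """Degenerate truth with one measurement age and known constant curves.

    In this mode the band reduces to raw order statistics of the draws and
    the one-sided confidence probabilities have the closed form of
    :func:`beta_exact_single_age`, which makes it the validation oracle for
    the Monte Carlo machinery.
    """

    class _Const:
        def __init__(self, v):
            self.v = v

        def __call__(self, t):
            t = np.asarray(t, dtype=float)
            out = np.full_like(t, self.v)
            return out if out.ndim else float(out)

    return ScenarioTruth(
        mean=_Const(mu),
        disp=mm.DispersionParams(gamma0=sigma, gamma1=0.0, t_lo=age, t_hi=age),
        baseline=baseline,
        grid=AgeGrid(np.array([age])),
        mean_model="constant",
    )


def beta_exact_single_age(n: int, tol: ToleranceSpec) -> float:
    """Closed-form one-sided confidence probability in the single-age case.

    With a single measurement age the boundary is a raw order statistic, and
    its attained coverage ``F(L_n)`` is distributed Beta(r, n - r + 1).  The
    window probability is then a difference of regularized incomplete beta
    functions.  Only the one-sided criteria admit this representation.
    """
    if tol.side == "two_sided":
        raise NotImplementedError("closed form available for one-sided criteria only")
    r_l, r_u = reference_ranks(n, tol.q)
    if tol.side == "lower":
        r, (lo, hi) = r_l, tol.lower_window
    else:
        r, (lo, hi) = r_u, tol.upper_window
    dist = stats.beta(r, n - r + 1)
    return float(dist.cdf(hi) - dist.cdf(lo))
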