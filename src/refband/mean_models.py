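"""Mean curves, dispersion function, and their least-squares estimation.

Two regression families describe the conditional mean ``mu(t)`` of the marker:

* a beta-cdf growth model ``mu(t) = c * (d + I_x(a, b))`` with
  ``x = (t - t_lo)/(t_hi - t_lo)`` and ``I_x(a, b)`` the regularized
  incomplete beta function — a bounded, monotone sigmoid suited to fetal
  biometry (Scenario I);
* a quartic polynomial ``mu(t) = a0 + a1 t + ... + a4 t^4`` (Scenario II).

The conditional scale is a line in scaled age, ``sigma(t) = g0 + g1 * s(t)``
with ``s(t) = (t - t_lo)/(t_hi - t_lo)``, estimated by regressing the
absolute residuals ``|Y_i - mu_hat(t_i)|`` on ``s(t_i)``.  Note that the
half-normal (or analogous) proportionality factor relating E|residual| to the
true scale never needs to be corrected for: the band construction is
invariant under positive rescaling of the dispersion estimate.

The growth model is fitted by variable projection: for fixed beta shapes
``(a, b)`` the model is linear in ``(c*d, c)``, so the linear pair is profiled
out analytically and only ``(a, b)`` are iterated.  This yields the same
minimizer as the full four-parameter OLS problem.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

__all__ = [
    "GrowthCurveParams",
    "PolyCurveParams",
    "DispersionParams",
    "growth_mu",
    "poly_mu",
    "fit_growth",
    "fit_poly",
    "fit_dispersion",
    "sigma_eval",
    "FitError",
]


class FitError(RuntimeError):
    """Raised when a least-squares fit cannot be completed."""


@dataclass(frozen=True)
class GrowthCurveParams:
    """Parameters of the beta-cdf growth model ``mu(t) = c(d + I_x(a, b))``."""

    a: float
    b: float
    c: float
    d: float
    t_lo: float
    t_hi: float
    converged: bool = True

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError("beta shapes a, b must be positive")
        if not self.c > 0:
            raise ValueError("scale c must be positive")
        if not self.t_lo < self.t_hi:
            raise ValueError("t_lo must be below t_hi")

    def __call__(self, t):
        return growth_mu(self, t)


@dataclass(frozen=True)
class PolyCurveParams:
    """Coefficients ``a0..a4`` of the quartic mean curve."""

    coeffs: tuple
    converged: bool = True

    def __post_init__(self) -> None:
        coeffs = tuple(float(c) for c in self.coeffs)
        if len(coeffs) != 5 or not np.all(np.isfinite(coeffs)):
            raise ValueError("quartic curve needs 5 finite coefficients")
        object.__setattr__(self, "coeffs", coeffs)

    def __call__(self, t):
        return poly_mu(self, t)


@dataclass(frozen=True)
class DispersionParams:
    """Linear dispersion ``sigma(t) = gamma0 + gamma1 * s(t)`` in scaled age."""

    gamma0: float
    gamma1: float
    t_lo: float
    t_hi: float

    def __call__(self, t):
        return sigma_eval(self, t)


def growth_mu(params: GrowthCurveParams, t):
    """Evaluate the growth-model mean curve at ages ``t`` in [t_lo, t_hi]."""
    t = np.asarray(t, dtype=float)
    if np.any((t < params.t_lo - 1e-12) | (t > params.t_hi + 1e-12)):
        raise ValueError("age outside the model range")
    x = np.clip((t - params.t_lo) / (params.t_hi - params.t_lo), 0.0, 1.0)
    out = params.c * (params.d + special.betainc(params.a, params.b, x))
    return out if out.ndim else float(out)


def poly_mu(params: PolyCurveParams, t):
    """Evaluate the quartic mean curve at ages ``t`` (Horner scheme)."""
    t = np.asarray(t, dtype=float)
    a0, a1, a2, a3, a4 = params.coeffs
    out = a0 + t * (a1 + t * (a2 + t * (a3 + t * a4)))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _growth_profile(ab, x_g, ybar_g, w_g):
    """Weighted residuals at grid level with (c*d, c) profiled out.

    Given shapes (a, b), the generating model is linear in beta0 = c*d and
    beta1 = c; solving that 2x2 weighted LS in closed form leaves residuals
    sqrt(w_g) * (ybar_g - beta0 - beta1 * B_g) over the distinct ages.
    """
    a, b = ab
    B = special.betainc(a, b, x_g)
    sw = w_g.sum()
    sB = w_g @ B
    sBB = w_g @ (B * B)
    sy = w_g @ ybar_g
    syB = w_g @ (ybar_g * B)
    det = sw * sBB - sB * sB
    if det <= 0 or not np.isfinite(det):
        return np.full_like(ybar_g, 1e6), (np.nan, np.nan)
    beta0 = (sBB * sy - sB * syB) / det
    beta1 = (sw * syB - sB * sy) / det
    r = np.sqrt(w_g) * (ybar_g - beta0 - beta1 * B)
    return r, (beta0, beta1)


def fit_growth(
    ages: np.ndarray,
    values: np.ndarray,
    init: GrowthCurveParams,
    *,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> GrowthCurveParams:
    """Ordinary least-squares fit of the beta-cdf growth model.

    Parameters
    ----------
    ages, values : array-like
        The observed (age, marker) pairs.
    init : GrowthCurveParams
        Starting values; in simulation studies these are the generating
        parameters, for user data a heuristic start is adequate.

    Returns
    -------
    GrowthCurveParams
        Fitted parameters with a ``converged`` flag.  The returned residual
        sum of squares never exceeds that of ``init``.

    Raises
    ------
    FitError
        If the design is degenerate (fewer than 5 distinct ages) or the
        profiled linear solve collapses.
    """
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(ages) < 10:
        raise FitError("need at least 10 observations to fit the growth model")
    t_uni, inv, cnt = np.unique(ages, return_inverse=True, return_counts=True)
    if len(t_uni) < 5:
        raise FitError("need at least 5 distinct ages to fit the growth model")
    x_g = (t_uni - init.t_lo) / (init.t_hi - init.t_lo)
    if np.any((x_g < -1e-12) | (x_g > 1 + 1e-12)):
        raise FitError("ages outside the model range [t_lo, t_hi]")
    x_g = np.clip(x_g, 0.0, 1.0)
    ybar_g = np.bincount(inv, weights=values, minlength=len(t_uni)) / cnt
    w_g = cnt.astype(float)

    res = optimize.least_squares(
        lambda ab: _growth_profile(ab, x_g, ybar_g, w_g)[0],
        x0=[init.a, init.b],
        bounds=([1e-8, 1e-8], [np.inf, np.inf]),
        xtol=tol,
        ftol=tol,
        gtol=tol,
        max_nfev=max_iter * 3,
    )
    a_hat, b_hat = res.x
    _, (beta0, beta1) = _growth_profile(res.x, x_g, ybar_g, w_g)
    if not np.isfinite(beta0) or not np.isfinite(beta1) or beta1 <= 0:
        raise FitError("profiled linear solve degenerate (non-positive scale)")
    return GrowthCurveParams(
        a=float(a_hat),
        b=float(b_hat),
        c=float(beta1),
        d=float(beta0 / beta1),
        t_lo=init.t_lo,
        t_hi=init.t_hi,
        converged=bool(res.status > 0),
    )


def default_growth_init(ages, values, t_lo: float, t_hi: float) -> GrowthCurveParams:
    """Heuristic start for user data: c from the Y range, d from its floor."""
    values = np.asarray(values, dtype=float)
    span = float(values.max() - values.min())
    c = span if span > 0 else 1.0
    d = max(float(values.min()) / c, 1e-6)
    return GrowthCurveParams(a=1.0, b=1.0, c=c, d=d, t_lo=t_lo, t_hi=t_hi)


def fit_poly(ages: np.ndarray, values: np.ndarray) -> PolyCurveParams:
    """OLS fit of the quartic mean curve.

    The design is orthogonalized on a centered/scaled age axis for numerical
    stability, then the coefficients are mapped back to raw powers of ``t``.
    """
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(ages) < 5 or len(np.unique(ages)) < 5:
        raise FitError("need at least 5 distinct ages to fit a quartic")
    # numpy's Polynomial fit works on a mapped domain internally
    series = np.polynomial.Polynomial.fit(ages, values, deg=4)
    coef = series.convert().coef
    coef = np.pad(coef, (0, 5 - len(coef)))
    if not np.all(np.isfinite(coef)):
        raise FitError("quartic design matrix is rank deficient")
    return PolyCurveParams(coeffs=tuple(coef))


def fit_dispersion(
    ages: np.ndarray,
    abs_residuals: np.ndarray,
    t_lo: float,
    t_hi: float,
    *,
    check_grid: np.ndarray | None = None,
) -> DispersionParams:
    """Least-squares line of absolute residuals on scaled age.

    Parameters
    ----------
    check_grid : array-like, optional
        Ages at which the fitted line must be strictly positive; violation
        raises :class:`FitError` (this is how a failed replicate surfaces in
        the Monte Carlo study).
    """
    ages = np.asarray(ages, dtype=float)
    av = np.asarray(abs_residuals, dtype=float)
    if len(ages) < 3:
        raise FitError("need at least 3 observations for the dispersion line")
    s = (ages - t_lo) / (t_hi - t_lo)
    ssum, s2sum, nn = s.sum(), (s * s).sum(), float(len(s))
    det = nn * s2sum - ssum * ssum
    if det <= 1e-14 * nn * max(s2sum, 1.0):
        # all ages (numerically) equal: constant dispersion
        g0, g1 = float(av.mean()), 0.0
    else:
        asum, assum = av.sum(), (av * s).sum()
        g0 = (s2sum * asum - ssum * assum) / det
        g1 = (nn * assum - ssum * asum) / det
    disp = DispersionParams(gamma0=float(g0), gamma1=float(g1), t_lo=t_lo, t_hi=t_hi)
    if check_grid is not None:
        vals = sigma_eval(disp, check_grid)
        if np.min(vals) <= 0:
            raise FitError("fitted dispersion line non-positive on the age grid")
    return disp


def sigma_eval(disp: DispersionParams, t):
    """Evaluate ``sigma(t) = gamma0 + gamma1 * s(t)``."""
    t = np.asarray(t, dtype=float)
    if disp.t_hi == disp.t_lo:  # degenerate single-age case
        s = np.zeros_like(t)
    else:
        s = (t - disp.t_lo) / (disp.t_hi - disp.t_lo)
    out = disp.gamma0 + disp.gamma1 * s
    return out if out.ndim else float(out)
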