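"""Built-in data-generating configurations for the two simulation scenarios.

Scenario I mimics a fetal-biometry study of the biparietal diameter:
beta-cdf growth-model mean curve on gestational weeks 10..41 with the
published point estimates as generating truth.  Scenario II mimics a study
of the frontal fetal facial angle: quartic mean curve on gestational days
77..280.  In both, the conditional scale is linear in scaled age and the
standardized residual follows one of four mean-zero baseline laws.
"""

from __future__ import annotations

import numpy as np

from .designs import make_grid
from .distributions import make_baseline
from .mean_models import DispersionParams, GrowthCurveParams, PolyCurveParams
from .confidence import ScenarioTruth

__all__ = [
    "SCENARIO_I_GROWTH",
    "SCENARIO_II_QUARTIC",
    "scenario_truth",
]

#: Generating growth-model parameters for Scenario I (biparietal diameter,
#: marker in mm, age in gestational weeks on [10, 41]).
SCENARIO_I_GROWTH = GrowthCurveParams(
    a=1.1494, b=1.5265, c=84.0244, d=0.1992, t_lo=10.0, t_hi=41.0
)

#: Generating quartic coefficients for Scenario II (frontal fetal facial
#: angle in degrees, age in gestational days on [77, 280]).
SCENARIO_II_QUARTIC = PolyCurveParams(
    coeffs=(275.548, -19.4763, 1.00317, -0.021839, 0.000171349)
)


def scenario_truth(
    scenario: str = "I",
    family: str = "gaussian",
    *,
    gamma0: float = 1.0,
    gamma1: float = 0.0,
    shape: dict | None = None,
) -> ScenarioTruth:
    """Assemble the data-generating truth for scenario ``"I"`` or ``"II"``.

    Parameters
    ----------
    family : str
        Baseline residual family (see :mod:`refband.distributions`).
    gamma0, gamma1 : float
        Intercept and slope of the dispersion line on scaled age
        ``s(t) in [0, 1]``; ``gamma1=0`` is the homoscedastic case.
    shape : dict, optional
        Shape parameters of the baseline law.
    """
    grid = make_grid(scenario)
    mean = SCENARIO_I_GROWTH if scenario == "I" else SCENARIO_II_QUARTIC
    disp = DispersionParams(gamma0=gamma0, gamma1=gamma1, t_lo=grid.t_lo, t_hi=grid.t_hi)
    sigma_grid = disp(grid.ages)
    if np.min(sigma_grid) <= 0:
        raise ValueError("dispersion line must be positive over the age grid")
    return ScenarioTruth(
        mean=mean,
        disp=disp,
        baseline=make_baseline(family, shape),
        grid=grid,
        mean_model="growth" if scenario == "I" else "quartic",
    )
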