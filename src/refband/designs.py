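"""Measurement-age grids and discretized-beta age designs.

Two study templates are built in:

* Scenario I — gestational age in weeks on the 218-point grid
  ``{10 + j/7 : 0 <= j <= 217}`` (weekly ultrasound schedule, 10..41 weeks);
* Scenario II — gestational age in days on the integer grid ``77..280``.

A realized design is the multiset of ages at which the ``n`` study subjects
are measured.  It is drawn once per Monte Carlo experiment from a beta(a*,b*)
law mapped onto the grid and then held fixed across all replications;
``a* = b* = 1`` denotes the fixed uniform design, which is allocated
deterministically (even spacing) rather than drawn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AgeGrid", "DesignSpec", "make_grid", "realize_design"]


@dataclass(frozen=True)
class AgeGrid:
    """Ordered set of candidate measurement ages.

    Attributes
    ----------
    ages : np.ndarray
        Strictly increasing ages ``t_1 < ... < t_K``.
    units : str
        ``"weeks"`` or ``"days"`` (informational).
    """

    ages: np.ndarray
    units: str = "units"

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        if ages.ndim != 1 or len(ages) < 1:
            raise ValueError("grid needs at least one age")
        if not np.all(np.diff(ages) > 0):
            raise ValueError("grid ages must be strictly increasing")
        object.__setattr__(self, "ages", ages)

    @property
    def t_lo(self) -> float:
        return float(self.ages[0])

    @property
    def t_hi(self) -> float:
        return float(self.ages[-1])

    def __len__(self) -> int:
        return len(self.ages)

    def scaled(self, t) -> np.ndarray:
        """Map ages to ``s(t) = (t - t_lo) / (t_hi - t_lo)`` in [0, 1]."""
        t = np.asarray(t, dtype=float)
        if self.t_hi == self.t_lo:  # degenerate single-age grid
            return np.zeros_like(t)
        return (t - self.t_lo) / (self.t_hi - self.t_lo)

    def snap(self, t) -> np.ndarray:
        """Snap arbitrary ages in range to the nearest grid point (ties low)."""
        t = np.asarray(t, dtype=float)
        if len(self.ages) == 1:
            return np.full_like(t, self.ages[0])
        idx = np.searchsorted(self.ages, t)
        idx = np.clip(idx, 1, len(self.ages) - 1)
        left = self.ages[idx - 1]
        right = self.ages[idx]
        # tie (exact midpoint) resolves to the lower grid point
        pick_right = (t - left) > (right - t)
        return np.where(pick_right, right, left)


@dataclass(frozen=True)
class DesignSpec:
    """Recipe for a realized age design.

    ``a_star = b_star = 1`` yields the fixed uniform design; other values draw
    ``n`` ages from a discretized beta(a*, b*) distribution on the grid.
    """

    n: int
    a_star: float
    b_star: float
    grid: AgeGrid
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not (self.a_star > 0 and self.b_star > 0):
            raise ValueError("beta design parameters must be positive")

    @property
    def is_uniform(self) -> bool:
        return self.a_star == 1.0 and self.b_star == 1.0


def make_grid(scenario: str) -> AgeGrid:
    """Return the built-in age grid for scenario ``"I"`` or ``"II"``."""
    if scenario == "I":
        return AgeGrid(10.0 + np.arange(218) / 7.0, units="weeks")
    if scenario == "II":
        return AgeGrid(np.arange(77, 281, dtype=float), units="days")
    raise ValueError(f"unknown scenario {scenario!r}; expected 'I' or 'II'")


def realize_design(spec: DesignSpec, *, random_uniform: bool = False) -> np.ndarray:
    """Realize the multiset of ``n`` measurement ages on the grid.

    For the uniform design the allocation is deterministic: age ``i`` is the
    grid point nearest to the ``(i - 0.5)/n`` quantile of the uniform law on
    the age range (set ``random_uniform=True`` to draw instead).  Non-uniform
    designs map beta(a*, b*) draws onto the age range and snap each to the
    nearest grid point; the draw is reproducible from ``spec.seed``.

    Returns
    -------
    np.ndarray
        Sorted ages of length ``n``, all lying on the grid.
    """
    grid = spec.grid
    if spec.is_uniform and not random_uniform:
        # even allocation over grid indices: subject i sits at the grid point
        # holding the (i - 0.5)/n quantile of the uniform law on the grid, so
        # n = m*K places every grid point exactly m times
        idx = np.floor(len(grid) * (np.arange(spec.n) + 0.5) / spec.n).astype(int)
        return np.sort(grid.ages[np.clip(idx, 0, len(grid) - 1)])
    else:
        rng = np.random.default_rng(spec.seed)
        u = rng.beta(spec.a_star, spec.b_star, spec.n)
        raw = grid.t_lo + u * (grid.t_hi - grid.t_lo)
    return np.sort(grid.snap(raw))


def design_table(ages: np.ndarray) -> "np.ndarray":
    """Summarize a realized design as (age, multiplicity) rows for audit."""
    vals, counts = np.unique(ages, return_counts=True)
    return np.column_stack([vals, counts.astype(float)])
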