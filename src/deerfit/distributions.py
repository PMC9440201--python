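"""Distance grids, Gaussian components and distance distributions.

Inter-spin-label distance distributions P(r) are represented on a uniform
distance grid (nm) and, when they come from a Gaussian-mixture fit, carry
their component parameterization (center, width, population) alongside the
discretized density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DistanceGrid",
    "GaussianComponent",
    "DistanceDistribution",
    "gaussian_mixture_density",
]

#: Default distance axis: the window over which nitroxide DEER is sensitive.
DEFAULT_R_MIN = 1.5
DEFAULT_R_MAX = 8.0
DEFAULT_R_STEP = 0.02


@dataclass(frozen=True)
class DistanceGrid:
    """Uniform distance axis in nm, inclusive of both endpoints."""

    r_min: float = DEFAULT_R_MIN
    r_max: float = DEFAULT_R_MAX
    step: float = DEFAULT_R_STEP

    def __post_init__(self) -> None:
        if not (self.r_min > 0):
            raise ValueError(f"r_min must be positive, got {self.r_min}")
        if not (self.step > 0):
            raise ValueError(f"step must be positive, got {self.step}")
        if self.r_max <= self.r_min:
            raise ValueError("r_max must exceed r_min")

    @property
    def values(self) -> np.ndarray:
        n = int(round((self.r_max - self.r_min) / self.step)) + 1
        return self.r_min + self.step * np.arange(n)

    def __len__(self) -> int:
        return int(round((self.r_max - self.r_min) / self.step)) + 1


@dataclass(frozen=True)
class GaussianComponent:
    """One Gaussian conformer population: center r0 (nm), width sigma (nm),
    population fraction a."""

    r0: float
    sigma: float
    population: float

    def __post_init__(self) -> None:
        if not (self.r0 > 0):
            raise ValueError(f"center must be positive, got {self.r0}")
        if not (self.sigma > 0):
            raise ValueError(f"width must be positive, got {self.sigma}")
        if not (0.0 <= self.population <= 1.0):
            raise ValueError(
                f"population must be a fraction in [0, 1], got {self.population}"
            )


def _component_density(grid_values: np.ndarray, r0: float, sigma: float) -> np.ndarray:
    """Gaussian density renormalized to unit trapezoidal integral on the grid.

    Per-component renormalization keeps populations exact even when a
    component's tails are truncated by the grid edges.
    """
    g = np.exp(-0.5 * ((grid_values - r0) / sigma) ** 2)
    z = np.trapezoid(g, grid_values)
    if z <= 0:
        raise ValueError(
            f"component at r0={r0} nm, sigma={sigma} nm has no support on the grid"
        )
    return g / z


def gaussian_mixture_density(
    grid: DistanceGrid, components: list[GaussianComponent]
) -> np.ndarray:
    """Density of a sum-of-Gaussians P(r) on `grid`; integrates to Σ populations."""
    r = grid.values
    density = np.zeros_like(r)
    for c in components:
        density += c.population * _component_density(r, c.r0, c.sigma)
    return density


@dataclass
class DistanceDistribution:
    """Discretized P(r) (1/nm) on a grid, optionally with its Gaussian
    components."""

    grid: DistanceGrid
    density: np.ndarray
    components: list[GaussianComponent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        if self.density.shape != self.grid.values.shape:
            raise ValueError("density and grid have mismatched lengths")
        if np.any(self.density < -1e-12):
            raise ValueError("density must be nonnegative")
        integral = np.trapezoid(self.density, self.grid.values)
        if abs(integral - 1.0) > 1e-6:
            raise ValueError(
                f"density must integrate to 1 (trapezoid), got {integral:.8f}"
            )
        if self.components:
            total = sum(c.population for c in self.components)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(
                    f"component populations must sum to 1, got {total:.8f}"
                )

    @classmethod
    def from_components(
        cls, components: list[GaussianComponent], grid: DistanceGrid | None = None
    ) -> "DistanceDistribution":
        grid = grid or DistanceGrid()
        total = sum(c.population for c in components)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"populations must sum to 1, got {total:.8f}")
        return cls(grid, gaussian_mixture_density(grid, components), list(components))

    @property
    def mean(self) -> float:
        r = self.grid.values
        return float(np.trapezoid(r * self.density, r))

    def resample(self, grid: DistanceGrid) -> "DistanceDistribution":
        """Linear resampling onto another grid, renormalized to unit integral."""
        r_new = grid.values
        p = np.interp(r_new, self.grid.values, self.density, left=0.0, right=0.0)
        z = np.trapezoid(p, r_new)
        if z <= 0:
            raise ValueError("distribution has no support on the target grid")
        return DistanceDistribution(grid, p / z, list(self.components))


def distribution_overlap(
    p_pred: DistanceDistribution, p_exp: DistanceDistribution
) -> float:
    """Overlap coefficient ∫ min(P1, P2) dr in [0, 1].

    1 iff the densities agree almost everywhere, 0 iff their supports are
    disjoint. Distributions on different grids are resampled onto the finer
    common axis first.
    """
    if p_pred.grid != p_exp.grid:
        fine = p_pred.grid if p_pred.grid.step <= p_exp.grid.step else p_exp.grid
        common = DistanceGrid(
            min(p_pred.grid.r_min, p_exp.grid.r_min),
            max(p_pred.grid.r_max, p_exp.grid.r_max),
            fine.step,
        )
        p_pred = p_pred.resample(common)
        p_exp = p_exp.resample(common)
    r = p_pred.grid.values
    return float(np.trapezoid(np.minimum(p_pred.density, p_exp.density), r))
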