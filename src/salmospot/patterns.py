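"""Planar point-pattern simulation for salmon spot arrangements.

Three generators cover the two regimes seen on fish flanks — numerous,
scattered-to-random spots (hatchery-reared fish) versus fewer spots grouped
into tight clumps (river-reared fish) — plus a homogeneous Poisson baseline:

* ``poisson`` — complete spatial randomness at a given intensity.
* ``thomas-cluster`` — a Thomas (Neyman–Scott) process: Poisson cluster
  parents, each with a Poisson number of offspring displaced by an isotropic
  Gaussian.  Produces clumped patterns.
* ``hard-core`` — simple sequential inhibition: points placed uniformly but
  rejected within ``min_dist`` of an accepted point.  Produces over-dispersed
  (scattered) patterns.

All coordinates and window dimensions are in centimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PointPattern", "PatternSpec", "gen_pattern"]

_PROCESSES = ("poisson", "thomas-cluster", "hard-core")


@dataclass(frozen=True)
class PointPattern:
    """Spot centroids in a rectangular observation window.

    Attributes
    ----------
    x, y : ndarray of float
        Point coordinates in cm, measured from the window's lower-left corner.
    width, height : float
        Window dimensions in cm.
    """

    x: np.ndarray
    y: np.ndarray
    width: float
    height: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.width <= 0 or self.height <= 0:
            raise ValueError("window dimensions must be positive")
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")

    @property
    def n(self) -> int:
        return self.x.size

    @property
    def area(self) -> float:
        """Window area in cm^2."""
        return self.width * self.height

    def coords(self) -> np.ndarray:
        """Return an (n, 2) array of (x, y) coordinates."""
        return np.column_stack([self.x, self.y])


@dataclass(frozen=True)
class PatternSpec:
    """Parameters of a synthetic spot pattern.

    ``intensity`` is the expected number of points per cm^2.  For the Thomas
    process it is the *offspring* intensity: parent intensity is
    ``intensity / mean_per_cluster``; alternatively set ``parent_intensity``
    directly (it then takes precedence).
    """

    width: float
    height: float
    process: str = "poisson"
    intensity: float = 1.0
    cluster_sd: float = 0.3
    mean_per_cluster: float = 8.0
    parent_intensity: float | None = None
    min_dist: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.process not in _PROCESSES:
            raise ValueError(f"process must be one of {_PROCESSES}, got {self.process!r}")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("window dimensions must be positive")
        if self.parent_intensity is None:
            if self.intensity <= 0:
                raise ValueError("intensity must be positive")
        elif self.parent_intensity <= 0:
            raise ValueError("parent_intensity must be positive")
        if self.process == "thomas-cluster":
            if self.cluster_sd < 0:
                raise ValueError("cluster_sd must be non-negative")
            if self.mean_per_cluster <= 0:
                raise ValueError("mean_per_cluster must be positive")
        if self.min_dist < 0:
            raise ValueError("min_dist must be non-negative")


def gen_pattern(spec: PatternSpec) -> PointPattern:
    """Simulate a point pattern according to ``spec``.

    Reproducible for a fixed ``spec.seed``.  For the hard-core process the
    target count is Poisson(intensity * area); if the inhibition distance
    makes the window too crowded, placement stops after a fixed attempt
    budget and the pattern contains the points placed so far.
    """
    rng = np.random.default_rng(spec.seed)
    w, h = spec.width, spec.height
    area = w * h

    if spec.process == "poisson":
        n = rng.poisson(spec.intensity * area)
        x = rng.uniform(0.0, w, size=n)
        y = rng.uniform(0.0, h, size=n)
        return PointPattern(x, y, w, h)

    if spec.process == "thomas-cluster":
        kappa = (
            spec.parent_intensity
            if spec.parent_intensity is not None
            else spec.intensity / spec.mean_per_cluster
        )
        # Parents simulated on a window expanded by 4 sd so edge clusters
        # contribute offspring inside the window (minimises edge thinning).
        pad = 4.0 * spec.cluster_sd
        n_parents = rng.poisson(kappa * (w + 2 * pad) * (h + 2 * pad))
        px = rng.uniform(-pad, w + pad, size=n_parents)
        py = rng.uniform(-pad, h + pad, size=n_parents)
        counts = rng.poisson(spec.mean_per_cluster, size=n_parents)
        cx = np.repeat(px, counts)
        cy = np.repeat(py, counts)
        x = cx + rng.normal(0.0, spec.cluster_sd, size=cx.size)
        y = cy + rng.normal(0.0, spec.cluster_sd, size=cy.size)
        inside = (x >= 0) & (x < w) & (y >= 0) & (y < h)
        return PointPattern(x[inside], y[inside], w, h)

    # hard-core: simple sequential inhibition
    target = rng.poisson(spec.intensity * area)
    xs: list[float] = []
    ys: list[float] = []
    max_attempts = 200 * max(target, 1)
    attempts = 0
    d2 = spec.min_dist**2
    while len(xs) < target and attempts < max_attempts:
        attempts += 1
        cx = rng.uniform(0.0, w)
        cy = rng.uniform(0.0, h)
        if xs and d2 > 0:
            ax = np.asarray(xs)
            ay = np.asarray(ys)
            if np.min((ax - cx) ** 2 + (ay - cy) ** 2) < d2:
                continue
        xs.append(cx)
        ys.append(cy)
    return PointPattern(np.asarray(xs), np.asarray(ys), w, h)
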