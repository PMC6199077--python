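"""Surface-metrology summaries on height maps: Ra, Rq, bearing curve, geometry."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import HeightMap

__all__ = [
    "BearingCurve",
    "PillarGeometry",
    "roughness",
    "bearing_fraction",
    "bearing_curve",
    "aspect_ratio",
    "subtract_plane",
]


def roughness(h: HeightMap) -> tuple[float, float]:
    """Area-wise roughness (Ra, Rq) in nm.

    Ra is the mean absolute deviation and Rq the root-mean-square deviation
    of heights from their mean; Rq >= Ra always (Cauchy–Schwarz).  A constant
    map gives (0, 0).
    """
    z = h.heights.ravel()
    if z.size < 2:
        raise ValueError("need at least two height samples")
    dev = z - z.mean()
    return float(np.abs(dev).mean()), float(np.sqrt((dev**2).mean()))


@dataclass(frozen=True)
class BearingCurve:
    """Abbott–Firestone (bearing-area) curve.

    ``fraction[k]`` is the fraction of the evaluated area whose height is at
    or above ``levels[k]``; levels descend from just above the summit (where
    the fraction is 0) to the lowest point (fraction 1).
    """

    levels: np.ndarray    # nm, strictly decreasing
    fraction: np.ndarray  # in [0, 1], non-decreasing


def bearing_fraction(h: HeightMap, level: float) -> float:
    """Fraction of the area at or above ``level`` (nm)."""
    return float((h.heights >= level).mean())


def bearing_curve(h: HeightMap, n_levels: int = 256) -> BearingCurve:
    """Bearing curve sampled on ``n_levels`` descending height levels.

    The topmost level sits one step above the summit so the curve spans the
    full [0, 1] range; for a perfectly flat map this degenerates to the step
    function 0 above / 1 at the surface height.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    z = h.heights
    zmax, zmin = float(z.max()), float(z.min())
    if zmax == zmin:
        levels = np.array([zmax + 1.0, zmax])
    else:
        step = (zmax - zmin) / (n_levels - 1)
        levels = np.linspace(zmax + step, zmin, n_levels)
    frac = np.array([bearing_fraction(h, lv) for lv in levels])
    return BearingCurve(levels, frac)


@dataclass(frozen=True)
class PillarGeometry:
    """Mean geometric descriptors of a pillar population (all in nm)."""

    height: float
    tip_width: float
    interpillar_distance: float

    def __post_init__(self) -> None:
        if min(self.height, self.tip_width, self.interpillar_distance) <= 0:
            raise ValueError("geometry parameters must be positive")

    @property
    def aspect_ratio(self) -> float:
        return aspect_ratio(self.height, self.tip_width)


def aspect_ratio(height: float, tip_width: float) -> float:
    """Pillar aspect ratio = height / tip width (dimensionless)."""
    if tip_width <= 0:
        raise ValueError("tip_width must be positive")
    return height / tip_width


def subtract_plane(h: HeightMap) -> HeightMap:
    """Remove the least-squares first-order plane (optional flatten step)."""
    z = h.heights
    ny, nx = z.shape
    y, x = np.mgrid[0:ny, 0:nx]
    A = np.column_stack([x.ravel(), y.ravel(), np.ones(z.size)])
    coef, *_ = np.linalg.lstsq(A, z.ravel(), rcond=None)
    plane = (A @ coef).reshape(z.shape)
    return HeightMap(z - plane, h.pixel_size_nm)
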