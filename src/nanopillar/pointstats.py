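"""Point-pattern statistics for pillar-tip sets.

The central quantity is the pair-correlation function

    g(R) = rho(R) / rho0,

the mean tip density at distance R from a typical tip, normalised by the
overall density rho0 so that g -> 1 at large distances for a structureless
(Poisson) pattern.  g vanishes inside the hard-core excluded area and shows a
first peak at the characteristic neighbour spacing.  The estimator bins all
pairwise distances into annuli and applies Ripley's isotropic edge
correction: each ordered pair (i -> j) at distance d is weighted by the
inverse fraction of the circle of radius d around i that lies inside the
field of view.  For a rectangular field and d below half the shorter side,
that fraction has the closed form implemented in :func:`_circle_inside_fraction`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .containers import TipSet

__all__ = [
    "PairCorrelation",
    "NeighborDistribution",
    "Peak",
    "density",
    "pair_correlation",
    "first_peak",
    "neighbor_distribution",
    "compare_neighbor_distributions",
]


def density(tips: TipSet) -> float:
    """Tip density in tips per µm² (count / field area)."""
    area = tips.area_nm2
    if area <= 0:
        raise ValueError("field area must be positive")
    return tips.n / (area * 1e-6)


@dataclass(frozen=True)
class PairCorrelation:
    """Binned pair-correlation estimate.

    ``pair_counts`` are the raw (unweighted, unordered) pair tallies per bin;
    ``g`` is the edge-corrected, density-normalised estimate.
    """

    bin_edges: np.ndarray   # nm, len = nbins + 1
    g: np.ndarray
    pair_counts: np.ndarray
    rho0: float             # tips / nm^2
    n_tips: int
    warnings: tuple[str, ...] = ()

    @property
    def r(self) -> np.ndarray:
        """Bin centres, nm."""
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


def _circle_inside_fraction(x: np.ndarray, y: np.ndarray, d: np.ndarray,
                            extent: tuple[float, float, float, float]) -> np.ndarray:
    """Fraction of the circle of radius d around (x, y) inside the rectangle.

    Valid for d <= min(width, height) / 2: then at most one of each opposite
    edge pair can cut the circle, at most two (adjacent) edges cut in total,
    and the union of the two exterior arcs overlaps only across their shared
    corner.  Exterior arc half-width for an edge at distance t < d is
    arccos(t / d); the adjacent-arc overlap is max(0, a + b - pi/2).
    """
    x0, y0, x1, y1 = extent
    with np.errstate(invalid="ignore"):
        a_l = np.arccos(np.clip((x - x0) / d, -1, 1))
        a_r = np.arccos(np.clip((x1 - x) / d, -1, 1))
        a_b = np.arccos(np.clip((y - y0) / d, -1, 1))
        a_t = np.arccos(np.clip((y1 - y) / d, -1, 1))
    for a in (a_l, a_r, a_b, a_t):
        np.nan_to_num(a, copy=False)
    exterior = 2.0 * (a_l + a_r + a_b + a_t)
    for ax, ay in ((a_l, a_b), (a_b, a_r), (a_r, a_t), (a_t, a_l)):
        exterior -= np.maximum(0.0, ax + ay - np.pi / 2.0)
    return 1.0 - exterior / (2.0 * np.pi)


def pair_correlation(tips: TipSet, bin_width: float = 20.0, r_max: float = 1000.0) -> PairCorrelation:
    """Edge-corrected pair-correlation estimate with annulus bins of ``bin_width``.

    Requires ``r_max`` at most half the shorter field side (the regime where
    the closed-form isotropic edge correction is exact).
    """
    if tips.n < 2:
        raise ValueError("need at least two tips")
    if bin_width <= 0 or r_max <= 0:
        raise ValueError("bin_width and r_max must be positive")
    if r_max > min(tips.width_nm, tips.height_nm) / 2 + 1e-9:
        raise ValueError("r_max must not exceed half the shorter field side")
    warnings: list[str] = []
    if tips.n < 30:
        warnings.append(f"only {tips.n} tips; normalisation is noisy")
    edges = np.arange(0.0, r_max + bin_width * 0.5, bin_width)
    if edges[-1] < r_max - 1e-9:
        edges = np.append(edges, r_max)
    nbins = len(edges) - 1

    pts = tips.xy
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r_max * (1 + 1e-12), output_type="ndarray")
    counts = np.zeros(nbins, dtype=np.int64)
    weighted = np.zeros(nbins)
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        d = np.linalg.norm(pts[j] - pts[i], axis=1)
        keep = d < r_max
        i, j, d = i[keep], j[keep], d[keep]
        idx = np.searchsorted(edges, d, side="right") - 1
        np.add.at(counts, idx, 1)
        # Ordered-pair weights: each unordered pair contributes once from each
        # endpoint, with the endpoint's own edge-correction weight.
        w_i = 1.0 / _circle_inside_fraction(pts[i, 0], pts[i, 1], d, tips.extent)
        w_j = 1.0 / _circle_inside_fraction(pts[j, 0], pts[j, 1], d, tips.extent)
        np.add.at(weighted, idx, w_i + w_j)

    rho0 = tips.n / tips.area_nm2
    annulus = np.pi * (edges[1:] ** 2 - edges[:-1] ** 2)
    g = weighted / (tips.n * rho0 * annulus)
    return PairCorrelation(edges, g, counts, rho0, tips.n, tuple(warnings))


@dataclass(frozen=True)
class Peak:
    """An interpolated local maximum, with the sub-bin parabola vertex."""

    position: float   # nm (or nm^-1 for spectra)
    height: float


def _parabolic_vertex(x: np.ndarray, y: np.ndarray, k: int) -> tuple[float, float]:
    """Vertex of the parabola through points k-1, k, k+1 (uniform spacing)."""
    if k == 0 or k == len(y) - 1:
        return float(x[k]), float(y[k])
    y0, y1, y2 = y[k - 1], y[k], y[k + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(x[k]), float(y[k])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -0.5, 0.5))
    h = float(x[k + 1] - x[k])
    return float(x[k] + delta * h), float(y1 - 0.25 * (y0 - y2) * delta)


def first_peak(g: PairCorrelation, min_R: float = 100.0) -> Peak | None:
    """First local maximum of g above 1 beyond ``min_R``, sub-bin interpolated.

    ``min_R`` excludes the hard-core excluded-area zone where g rises from 0.
    Returns None when no bin beyond ``min_R`` is a local maximum above 1.
    """
    r = g.r
    vals = g.g
    start = int(np.searchsorted(r, min_R))
    for k in range(max(start, 1), len(vals) - 1):
        if vals[k] > 1.0 and vals[k] >= vals[k - 1] and vals[k] >= vals[k + 1]:
            pos, height = _parabolic_vertex(r, vals, k)
            return Peak(pos, height)
    return None


@dataclass(frozen=True)
class NeighborDistribution:
    """Per-tip neighbour counts within ``cutoff`` for interior tips.

    Tips within ``cutoff`` of the field border are excluded from the count
    statistic (minus sampling) but still count as neighbours of interior tips.
    """

    cutoff: float
    counts: np.ndarray        # one entry per interior tip
    histogram: np.ndarray     # histogram[k] = number of interior tips with k neighbours
    mean: float

    @property
    def n_tips(self) -> int:
        return int(self.counts.size)


def neighbor_distribution(tips: TipSet, cutoff: float = 500.0) -> NeighborDistribution:
    """Distribution of the number of neighbours within ``cutoff`` nm of each tip."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    x0, y0, x1, y1 = tips.extent
    pts = tips.xy
    interior = (
        (pts[:, 0] >= x0 + cutoff)
        & (pts[:, 0] <= x1 - cutoff)
        & (pts[:, 1] >= y0 + cutoff)
        & (pts[:, 1] <= y1 - cutoff)
    )
    if pts.shape[0] == 0 or not interior.any():
        return NeighborDistribution(cutoff, np.zeros(0, int), np.zeros(1, int), float("nan"))
    tree = cKDTree(pts)
    counts = np.array(
        [len(tree.query_ball_point(p, cutoff)) - 1 for p in pts[interior]], dtype=int
    )
    hist = np.bincount(counts)
    return NeighborDistribution(cutoff, counts, hist, float(counts.mean()))


@dataclass(frozen=True)
class DominanceReport:
    """First-order stochastic dominance comparison of two neighbour distributions."""

    mean_a: float
    mean_b: float
    b_dominates_a: bool    # distribution b stochastically larger than a
    identical: bool


def compare_neighbor_distributions(
    a: NeighborDistribution, b: NeighborDistribution
) -> DominanceReport:
    """Check whether ``b`` is shifted toward larger neighbour counts than ``a``.

    ``b`` first-order dominates ``a`` when its empirical CDF lies at or below
    ``a``'s everywhere and strictly below it somewhere.
    """
    kmax = max(len(a.histogram), len(b.histogram))
    pa = np.zeros(kmax)
    pb = np.zeros(kmax)
    pa[: len(a.histogram)] = a.histogram / max(a.histogram.sum(), 1)
    pb[: len(b.histogram)] = b.histogram / max(b.histogram.sum(), 1)
    cdf_a, cdf_b = np.cumsum(pa), np.cumsum(pb)
    identical = bool(np.allclose(cdf_a, cdf_b))
    dominates = bool(
        not identical and np.all(cdf_b <= cdf_a + 1e-12) and np.any(cdf_b < cdf_a - 1e-12)
    )
    return DominanceReport(a.mean, b.mean, dominates, identical)
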