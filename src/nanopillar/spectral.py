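"""Tiled averaged-FFT analysis of micrographs and radial spectra.

An isotropic short-range-ordered surface shows no Bragg spots but a broad
"halo" ring in its 2-D Fourier magnitude at the wave number of the
characteristic spacing.  The analysis averages the magnitude spectra of
overlapping square tiles (which suppresses speckle variance without blurring
the ring), radially averages the result, and locates the halo peak.

Wave numbers use the 2π convention, q = 2π / R (nm⁻¹), which maps a 306-nm
spacing to q ≈ 0.0205 nm⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import Micrograph
from .pointstats import Peak, _parabolic_vertex

__all__ = [
    "AveragedFFT",
    "RadialSpectrum",
    "tiled_fft",
    "radial_average",
    "halo_peak",
    "q_to_R",
    "R_to_q",
]


@dataclass(frozen=True)
class AveragedFFT:
    """Mean DC-centred magnitude spectrum over overlapping tiles."""

    magnitude: np.ndarray     # (tile, tile), non-negative
    tile: int
    stride: int
    n_tiles: int
    pixel_size_nm: float
    dc_mean_magnitude: float  # original mean DC magnitude (before replacement)


@dataclass(frozen=True)
class RadialSpectrum:
    """Radially averaged magnitude vs wave number q (nm⁻¹, 2π convention)."""

    q: np.ndarray
    magnitude: np.ndarray


def tiled_fft(
    image: Micrograph, tile: int = 512, stride: int = 100, window: str | None = None
) -> AveragedFFT:
    """Average the FFT magnitude over all tiles fitting into the image.

    Tiles sit on a stride grid anchored at the top-left corner; partial tiles
    are discarded.  The DC (centre) pixel of the averaged spectrum is replaced
    by the mean of its 8 neighbours, which otherwise dwarfs the display range.
    ``window='hann'`` applies a separable Hann taper per tile (off by default).
    """
    h, w = image.shape
    if h < tile or w < tile:
        raise ValueError(f"image {h}x{w} is smaller than one {tile}x{tile} tile")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if window not in (None, "hann"):
        raise ValueError("window must be None or 'hann'")
    taper = None
    if window == "hann":
        hann = np.hanning(tile)
        taper = np.outer(hann, hann)
    acc = np.zeros((tile, tile))
    n_tiles = 0
    for i0 in range(0, h - tile + 1, stride):
        for j0 in range(0, w - tile + 1, stride):
            patch = image.data[i0 : i0 + tile, j0 : j0 + tile]
            if taper is not None:
                patch = patch * taper
            acc += np.abs(np.fft.fftshift(np.fft.fft2(patch)))
            n_tiles += 1
    mean = acc / n_tiles
    c = tile // 2
    dc_mean = float(mean[c, c])
    neigh = mean[c - 1 : c + 2, c - 1 : c + 2]
    mean[c, c] = (neigh.sum() - mean[c, c]) / 8.0
    return AveragedFFT(mean, tile, stride, n_tiles, image.pixel_size_nm, dc_mean)


def _q_grid(tile: int, pixel_size_nm: float) -> np.ndarray:
    f = np.fft.fftshift(np.fft.fftfreq(tile))  # cycles / px
    fx, fy = np.meshgrid(f, f)
    return 2.0 * np.pi * np.hypot(fx, fy) / pixel_size_nm


def radial_average(fft: AveragedFFT, n_bins: int | None = None) -> RadialSpectrum:
    """Mean magnitude over annuli of constant |q|.

    Bins are uniform from 0 to the Nyquist wave number π/pixel_size; the DC
    pixel is excluded, and empty bins are dropped, so q is strictly positive
    and increasing.
    """
    if n_bins is None:
        n_bins = fft.tile // 2
    q = _q_grid(fft.tile, fft.pixel_size_nm)
    q_max = np.pi / fft.pixel_size_nm
    edges = np.linspace(0.0, q_max, n_bins + 1)
    flat_q = q.ravel()
    flat_m = fft.magnitude.ravel()
    keep = (flat_q > 0) & (flat_q <= q_max)
    idx = np.clip(np.searchsorted(edges, flat_q[keep], side="right") - 1, 0, n_bins - 1)
    sums = np.bincount(idx, weights=flat_m[keep], minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    centres = 0.5 * (edges[:-1] + edges[1:])
    nonempty = counts > 0
    return RadialSpectrum(centres[nonempty], sums[nonempty] / counts[nonempty])


def halo_peak(spec: RadialSpectrum, q_min: float = 0.008) -> Peak | None:
    """Wave number of maximal magnitude beyond ``q_min``, sub-bin interpolated.

    ``q_min`` excludes the low-q envelope (tile-scale intensity gradients).
    Returns None for a spectrum that is monotone beyond ``q_min`` (the
    maximum sits at the window edge), i.e. no halo.
    """
    mask = spec.q >= q_min
    if not mask.any():
        raise ValueError("q_min excludes the whole spectrum")
    qs = spec.q[mask]
    ms = spec.magnitude[mask]
    k = int(np.argmax(ms))
    if k == 0 or k == len(ms) - 1:
        return None
    pos, height = _parabolic_vertex(qs, ms, k)
    return Peak(pos, height)


def q_to_R(q: float) -> float:
    """Real-space length R = 2π/q (q in nm⁻¹, R in nm)."""
    if q <= 0:
        raise ValueError("q must be positive")
    return 2.0 * np.pi / q


def R_to_q(R: float) -> float:
    """Wave number q = 2π/R (R in nm, q in nm⁻¹)."""
    if R <= 0:
        raise ValueError("R must be positive")
    return 2.0 * np.pi / R
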