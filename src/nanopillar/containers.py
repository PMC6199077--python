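"""Shared data containers and their plain-text / image file formats.

All physical coordinates and lengths are in nanometres; images carry a
``pixel_size_nm`` calibration stored in a sidecar JSON next to the image file
so that detection and spectral analysis can report results in physical units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

#: Axis-aligned rectangle (xmin, ymin, xmax, ymax) in nm.
Rect = tuple[float, float, float, float]


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


@dataclass(frozen=True)
class TipSet:
    """Pillar-tip coordinates (nm) together with the field of view they live in.

    Parameters
    ----------
    xy
        ``(n, 2)`` array of ``(x, y)`` coordinates in nm.
    extent
        ``(xmin, ymin, xmax, ymax)`` rectangle, nm.  Every point must lie
        inside (a small numerical tolerance is allowed at the border).
    """

    xy: np.ndarray
    extent: Rect

    def __post_init__(self) -> None:
        xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "xy", xy)
        x0, y0, x1, y1 = self.extent
        if not (x1 > x0 and y1 > y0):
            raise ValueError(f"degenerate extent {self.extent!r}")
        if xy.size and (
            xy[:, 0].min() < x0 - 1e-6
            or xy[:, 0].max() > x1 + 1e-6
            or xy[:, 1].min() < y0 - 1e-6
            or xy[:, 1].max() > y1 + 1e-6
        ):
            raise ValueError("tip coordinates outside the stated extent")

    @property
    def n(self) -> int:
        return int(self.xy.shape[0])

    @property
    def width_nm(self) -> float:
        return self.extent[2] - self.extent[0]

    @property
    def height_nm(self) -> float:
        return self.extent[3] - self.extent[1]

    @property
    def area_nm2(self) -> float:
        return self.width_nm * self.height_nm

    def to_csv(self, path: str | Path, extent_path: str | Path | None = None) -> None:
        """Write ``x_nm,y_nm`` CSV plus an extent sidecar JSON."""
        path = Path(path)
        pd.DataFrame(self.xy, columns=["x_nm", "y_nm"]).to_csv(path, index=False)
        extent_path = Path(extent_path) if extent_path else _sidecar_path(path)
        extent_path.write_text(
            json.dumps({"extent_nm": list(self.extent)}, indent=1) + "\n"
        )

    @classmethod
    def from_csv(cls, path: str | Path, extent_path: str | Path | None = None) -> "TipSet":
        path = Path(path)
        df = pd.read_csv(path)
        extent_path = Path(extent_path) if extent_path else _sidecar_path(path)
        meta = json.loads(Path(extent_path).read_text())
        return cls(df[["x_nm", "y_nm"]].to_numpy(float), tuple(meta["extent_nm"]))


@dataclass(frozen=True)
class Micrograph:
    """A calibrated 2-D grayscale intensity field.

    ``data`` is indexed ``[row, col]``; row maps to y, col to x.  Gray levels
    are stored as floats (typically on an 8-bit-like 0–255 scale).
    """

    data: np.ndarray
    pixel_size_nm: float

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError("micrograph data must be 2-D grayscale")
        if not np.isfinite(data).all():
            raise ValueError("micrograph contains non-finite intensities")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        object.__setattr__(self, "data", data)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]

    def save(self, path: str | Path) -> None:
        """Write TIFF (float32, lossless) or PNG (8-bit) plus calibration sidecar."""
        path = Path(path)
        if path.suffix.lower() in {".tif", ".tiff"}:
            tifffile.imwrite(path, self.data.astype(np.float32))
        elif path.suffix.lower() == ".png":
            arr = np.clip(np.round(self.data), 0, 255).astype(np.uint8)
            Image.fromarray(arr, mode="L").save(path)
        else:
            raise ValueError(f"unsupported image format: {path.suffix}")
        _sidecar_path(path).write_text(
            json.dumps({"pixel_size_nm": self.pixel_size_nm}) + "\n"
        )

    @classmethod
    def load(cls, path: str | Path, pixel_size_nm: float | None = None) -> "Micrograph":
        path = Path(path)
        if path.suffix.lower() in {".tif", ".tiff"}:
            data = tifffile.imread(path)
        else:
            data = np.asarray(Image.open(path).convert("L"))
        if pixel_size_nm is None:
            meta = json.loads(_sidecar_path(path).read_text())
            pixel_size_nm = float(meta["pixel_size_nm"])
        return cls(np.asarray(data, float), pixel_size_nm)


@dataclass(frozen=True)
class HeightMap:
    """AFM-style height field in nm with a lateral pixel-size calibration."""

    heights: np.ndarray
    pixel_size_nm: float

    def __post_init__(self) -> None:
        h = np.asarray(self.heights, dtype=float)
        if h.ndim != 2:
            raise ValueError("height map must be 2-D")
        if not np.isfinite(h).all():
            raise ValueError("height map contains non-finite values")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        object.__setattr__(self, "heights", h)

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        np.savetxt(path, self.heights, delimiter=",", fmt="%.6g")
        _sidecar_path(path).write_text(
            json.dumps({"pixel_size_nm": self.pixel_size_nm, "units": "nm"}) + "\n"
        )

    @classmethod
    def from_csv(cls, path: str | Path, pixel_size_nm: float | None = None) -> "HeightMap":
        path = Path(path)
        h = np.loadtxt(path, delimiter=",", ndmin=2)
        if pixel_size_nm is None:
            meta = json.loads(_sidecar_path(path).read_text())
            pixel_size_nm = float(meta["pixel_size_nm"])
        return cls(h, pixel_size_nm)
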