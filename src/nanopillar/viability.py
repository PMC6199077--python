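"""Bactericidal-efficiency estimation from paired plate counts.

Colony-forming units (CFU) on a control surface and on the nanostructured
surface after the same incubation are treated as live-cell counts.  The
bactericidal efficiency of a surface is

    (control CFU − surface CFU) / (area · incubation time)

in cells killed per minute per cm², computed per replicate and summarised as
mean ± SEM with a two-tailed paired Student's t test between control and
surface counts.  p < 0.05 is reported as significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ViabilityTable",
    "EfficiencyResult",
    "TTestResult",
    "efficiency",
    "dead_fraction",
    "paired_t_test",
]


@dataclass(frozen=True)
class ViabilityTable:
    """Per-replicate paired CFU counts plus assay geometry.

    ``counts`` must have columns ``replicate``, ``control_cfu``,
    ``surface_cfu`` and may carry a ``dilution`` column (plate dilution
    factor; CFU are multiplied by it; defaults to 1).
    """

    counts: pd.DataFrame
    area_cm2: float
    incubation_min: float
    strain: str = ""

    def __post_init__(self) -> None:
        required = {"replicate", "control_cfu", "surface_cfu"}
        missing = required - set(self.counts.columns)
        if missing:
            raise ValueError(f"counts table missing columns: {sorted(missing)}")
        if len(self.counts) < 1:
            raise ValueError("need at least one replicate")
        if (self.counts[["control_cfu", "surface_cfu"]] < 0).any().any():
            raise ValueError("CFU counts must be non-negative")
        if self.area_cm2 <= 0 or self.incubation_min <= 0:
            raise ValueError("area and incubation must be positive")

    def scaled_counts(self) -> tuple[np.ndarray, np.ndarray]:
        dil = (
            self.counts["dilution"].to_numpy(float)
            if "dilution" in self.counts.columns
            else 1.0
        )
        return (
            self.counts["control_cfu"].to_numpy(float) * dil,
            self.counts["surface_cfu"].to_numpy(float) * dil,
        )


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: int
    error: str | None = None


def paired_t_test(x, y) -> TTestResult:
    """Two-tailed paired Student's t test on the differences y − x.

    Degenerate cases: identical samples give (t=0, p=1); constant nonzero
    differences have zero variance and are returned as an error result.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 2:
        raise ValueError("need at least two pairs")
    d = y - x
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return TTestResult(0.0, 1.0, x.size - 1)
        return TTestResult(
            float("nan"), float("nan"), x.size - 1,
            error="zero-variance differences: t is undefined (all pairs shifted "
                  "by the same amount)",
        )
    res = stats.ttest_rel(y, x)
    return TTestResult(float(res.statistic), float(res.pvalue), x.size - 1)


@dataclass(frozen=True)
class EfficiencyResult:
    """Bactericidal efficiency summary (cells killed · min⁻¹ · cm⁻²)."""

    per_replicate: np.ndarray
    mean: float
    sem: float
    dead_fraction: float
    t_test: TTestResult | None
    negative_replicates: int

    @property
    def significant(self) -> bool | None:
        if self.t_test is None or not np.isfinite(self.t_test.p):
            return None
        return self.t_test.p < 0.05


def efficiency(v: ViabilityTable) -> EfficiencyResult:
    """Per-replicate and summary bactericidal efficiency.

    Negative per-replicate values (surface counts exceeding the paired
    control) are retained and flagged rather than truncated, since truncation
    would bias the mean upward.  With one replicate the SEM is reported as 0.
    """
    control, surface = v.scaled_counts()
    per = (control - surface) / (v.area_cm2 * v.incubation_min)
    n = per.size
    sem = float(per.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    total_c = control.sum()
    dead = float(np.clip(1.0 - surface.sum() / total_c, 0.0, 1.0)) if total_c > 0 else float("nan")
    t_res = paired_t_test(surface, control) if n >= 2 else None
    return EfficiencyResult(
        per_replicate=per,
        mean=float(per.mean()),
        sem=sem,
        dead_fraction=dead,
        t_test=t_res,
        negative_replicates=int((per < 0).sum()),
    )


def dead_fraction(live: float, dead: float) -> float:
    """Fraction of dead cells, dead / (live + dead)."""
    if live < 0 or dead < 0:
        raise ValueError("counts must be non-negative")
    if live + dead == 0:
        raise ValueError("live + dead must be positive")
    return dead / (live + dead)
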