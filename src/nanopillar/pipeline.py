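"""End-to-end orchestration: synthesize → (train →) detect → statistics → report.

A run is described by a single JSON-serialisable :class:`RunConfig` with one
namespaced block per stage and an explicit seed for every random stage, so a
run is deterministic given its config.  Each surface yields a
:class:`SurfaceReport` (density, pair-correlation peak, spectral halo,
neighbour statistics, roughness, geometry, bactericidal efficiency) with
provenance (config hash, seeds, package version);
:func:`compare_surfaces` lines reports up side by side and rank-correlates
efficiency against each topographic parameter.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field
from scipy import stats as _scipy_stats

from . import __version__
from . import detector, pointstats, spectral, synth, topography, viability
from .containers import Micrograph, TipSet

logger = logging.getLogger("nanopillar.pipeline")

__all__ = [
    "RunConfig",
    "SurfaceConfig",
    "SurfaceReport",
    "ComparisonTable",
    "PipelineError",
    "run_pipeline",
    "compare_surfaces",
    "config_hash",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PatternConfig(_Strict):
    density: float = 10.0
    exclusion_radius: float = 150.0
    spacing: float | None = 306.0
    jitter_sd: float = 10.0
    bundle_prob: float = 0.0
    # 10x10 um so the rendered image (1000x1000 px at 10 nm/px) holds 512-px
    # FFT tiles with the default spectral settings
    field_width: float = 10_000.0
    field_height: float = 10_000.0
    seed: int = 0


class RenderConfig(_Strict):
    pixel_size_nm: float = 10.0
    tip_width_nm: float = 110.0
    peak_intensity: float = 180.0
    background_level: float = 40.0
    noise_sd: float = 8.0
    seed: int = 0


class HeightConfig(_Strict):
    height_mean: float = 836.8
    height_sd: float = 91.2
    pixel_size_nm: float = 10.0
    footprint_sigma_nm: float = 60.0
    seed: int = 0


class ViabilityConfig(_Strict):
    inoculum_cfu: float = 1.0e6
    kill_fraction: float = 0.9
    area_cm2: float = 1.0
    incubation_min: float = 180.0
    replicates: int = 5
    count_noise_cv: float = 0.10
    seed: int = 0


class DetectorConfig(_Strict):
    enabled: bool = False          # off: statistics run on ground-truth tips
    n_train_per_class: int = 7
    passes_per_pattern: int = 150
    learning_rate: float = 0.1
    stride: int = 1
    threshold: float = 0.5
    min_separation_nm: float = 110.0
    seed: int = 0


class StatsConfig(_Strict):
    bin_width: float = 20.0
    r_max: float = 1000.0
    min_r_peak: float = 100.0
    neighbor_cutoff: float = 500.0


class SpectralConfig(_Strict):
    enabled: bool = True
    tile: int = 512
    stride: int = 100
    q_min: float = 0.008


class SurfaceConfig(_Strict):
    name: str
    pattern: PatternConfig = Field(default_factory=PatternConfig)
    render: RenderConfig = Field(default_factory=RenderConfig)
    height: HeightConfig = Field(default_factory=HeightConfig)
    viability: ViabilityConfig = Field(default_factory=ViabilityConfig)


class RunConfig(_Strict):
    """Full pipeline configuration; every random stage carries its own seed."""

    schema_version: int = 1
    surfaces: list[SurfaceConfig]
    detector: DetectorConfig = Field(default_factory=DetectorConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)
    spectral: SpectralConfig = Field(default_factory=SpectralConfig)
    save_images: bool = True

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


@dataclass(frozen=True)
class SurfaceReport:
    """Per-surface summary with provenance; every value is produced by one stage."""

    name: str
    n_tips: int
    density_per_um2: float
    tips_source: str              # "detector" or "ground_truth"
    r_peak_nm: float | None
    g_peak: float | None
    q_peak_per_nm: float | None
    neighbor_mean: float
    ra_nm: float
    rq_nm: float
    height_mean_nm: float
    tip_width_nm: float
    aspect_ratio: float
    efficiency_mean: float
    efficiency_sem: float
    dead_fraction: float
    t_statistic: float | None
    p_value: float | None
    provenance: dict

    def to_dict(self) -> dict:
        return asdict(self)


def _stage(name: str, detail: str = ""):
    logger.info("stage %s %s", name, detail)


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> list[SurfaceReport]:
    """Run all stages for every configured surface; optionally write artifacts.

    With ``out_dir`` set, intermediates (tips CSV, rendered image, g(R) CSV,
    radial spectrum CSV, height map CSV, viability CSV) and the final
    ``report.json`` are written there.  Any stage failure raises
    :class:`PipelineError` naming the stage.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    reports: list[SurfaceReport] = []
    run_log: list[dict] = []
    for sc in config.surfaces:
        reports.append(_run_surface(sc, config, chash, out, run_log))
    if out is not None:
        (out / "report.json").write_text(
            json.dumps([r.to_dict() for r in reports], indent=1, sort_keys=True) + "\n"
        )
        (out / "run_log.jsonl").write_text(
            "".join(json.dumps(e) + "\n" for e in run_log)
        )
    return reports


def _timed(run_log: list[dict], surface: str, stage: str, fn, *args, **kwargs):
    t0 = time.perf_counter()
    try:
        result = fn(*args, **kwargs)
    except Exception as exc:
        raise PipelineError(f"stage '{stage}' failed for surface '{surface}': {exc}") from exc
    run_log.append(
        {"surface": surface, "stage": stage, "seconds": round(time.perf_counter() - t0, 4)}
    )
    _stage(stage, surface)
    return result


def _run_surface(
    sc: SurfaceConfig,
    config: RunConfig,
    chash: str,
    out: Path | None,
    run_log: list[dict],
) -> SurfaceReport:
    pat = synth.PatternSpec(**sc.pattern.model_dump())
    truth = _timed(run_log, sc.name, "pattern", synth.generate_pattern, pat)
    rspec = synth.RenderSpec(**sc.render.model_dump())
    image = _timed(run_log, sc.name, "render", synth.render_micrograph, truth, rspec)

    if config.detector.enabled:
        dc = config.detector
        base, labels = detector.sample_training_patches(
            image, truth, n_per_class=dc.n_train_per_class, seed=dc.seed
        )
        tset = detector.augment_training_set(base, labels)
        net = detector.NetworkWeights.initialize(seed=dc.seed)
        net = _timed(
            run_log, sc.name, "train", detector.train,
            net, tset.X, tset.labels, dc.passes_per_pattern, dc.learning_rate, dc.seed,
        )
        resp = _timed(run_log, sc.name, "scan", detector.scan, net, image, dc.stride)
        tips = detector.detect_tips(resp, dc.threshold, dc.min_separation_nm)
        tips_source = "detector"
    else:
        tips = truth
        tips_source = "ground_truth"

    st = config.stats
    dens = pointstats.density(tips)
    g = _timed(run_log, sc.name, "pair_correlation", pointstats.pair_correlation,
               tips, st.bin_width, st.r_max)
    peak = pointstats.first_peak(g, st.min_r_peak)
    nd = pointstats.neighbor_distribution(tips, st.neighbor_cutoff)

    q_peak = None
    radial = None
    if config.spectral.enabled:
        fft = _timed(run_log, sc.name, "tiled_fft", spectral.tiled_fft,
                     image, config.spectral.tile, config.spectral.stride)
        radial = spectral.radial_average(fft)
        halo = spectral.halo_peak(radial, config.spectral.q_min)
        q_peak = None if halo is None else halo.position

    hc = sc.height
    hmap = _timed(
        run_log, sc.name, "height_map", synth.generate_height_map,
        truth, hc.height_mean, hc.height_sd, hc.pixel_size_nm, hc.seed,
        hc.footprint_sigma_nm,
    )
    ra, rq = topography.roughness(hmap)
    aspect = topography.aspect_ratio(hc.height_mean, rspec.tip_width_nm)

    vspec = synth.ViabilitySpec(**sc.viability.model_dump())
    vtab = _timed(run_log, sc.name, "viability", synth.generate_viability, vspec)
    table = viability.ViabilityTable(vtab, vspec.area_cm2, vspec.incubation_min, sc.name)
    eff = viability.efficiency(table)

    if out is not None:
        tips.to_csv(out / f"{sc.name}_tips.csv")
        if config.save_images:
            image.save(out / f"{sc.name}_image.tif")
        pd.DataFrame({"r_nm": g.r, "g": g.g, "pairs": g.pair_counts}).to_csv(
            out / f"{sc.name}_gr.csv", index=False
        )
        if radial is not None:
            pd.DataFrame({"q_per_nm": radial.q, "magnitude": radial.magnitude}).to_csv(
                out / f"{sc.name}_radial.csv", index=False
            )
        hmap.to_csv(out / f"{sc.name}_heightmap.csv")
        vtab.to_csv(out / f"{sc.name}_viability.csv", index=False)

    t_res = eff.t_test
    return SurfaceReport(
        name=sc.name,
        n_tips=tips.n,
        density_per_um2=dens,
        tips_source=tips_source,
        r_peak_nm=None if peak is None else peak.position,
        g_peak=None if peak is None else peak.height,
        q_peak_per_nm=q_peak,
        neighbor_mean=nd.mean,
        ra_nm=ra,
        rq_nm=rq,
        height_mean_nm=hc.height_mean,
        tip_width_nm=rspec.tip_width_nm,
        aspect_ratio=aspect,
        efficiency_mean=eff.mean,
        efficiency_sem=eff.sem,
        dead_fraction=eff.dead_fraction,
        t_statistic=None if t_res is None else t_res.t,
        p_value=None if t_res is None else t_res.p,
        provenance={
            "config_hash": chash,
            "schema_version": config.schema_version,
            "package_version": __version__,
            "seeds": {
                "pattern": sc.pattern.seed,
                "render": sc.render.seed,
                "height": sc.height.seed,
                "viability": sc.viability.seed,
                "detector": config.detector.seed,
            },
        },
    )


_CORRELATES = ["density_per_um2", "height_mean_nm", "aspect_ratio", "ra_nm", "rq_nm"]


@dataclass(frozen=True)
class ComparisonTable:
    """Side-by-side metric table plus efficiency-vs-topography rank correlations."""

    table: pd.DataFrame                      # rows = metrics, cols = surfaces
    correlations: dict[str, float | None]    # Spearman rho vs efficiency_mean
    zero_variance: tuple[str, ...]


def compare_surfaces(reports: list[SurfaceReport]) -> ComparisonTable:
    """Tabulate reports and rank-correlate efficiency with each surface metric.

    Metrics with zero variance across the compared surfaces are flagged and
    their correlation reported as None (undefined).
    """
    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    df = pd.DataFrame([r.to_dict() for r in reports]).set_index("name")
    df = df.drop(columns=["provenance"])
    numeric = df.select_dtypes("number")
    eff = numeric["efficiency_mean"]
    zero_var: list[str] = [c for c in numeric.columns if numeric[c].nunique() <= 1]
    correlations: dict[str, float | None] = {}
    for col in _CORRELATES:
        if col in zero_var or "efficiency_mean" in zero_var:
            correlations[col] = None
            continue
        rho = _scipy_stats.spearmanr(eff, numeric[col]).statistic
        correlations[col] = None if not np.isfinite(rho) else float(rho)
    return ComparisonTable(df.T, correlations, tuple(zero_var))


def setup_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO if verbose else logging.WARNING)
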