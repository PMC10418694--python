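"""Run orchestration: config parsing, condition runs, condition comparison.

A run is fully described by one YAML config (all keys optional — defaults
reproduce the packaged study conditions) plus a seed; every output is a
deterministic function of the two.  Stages are file-to-file so they can be
run and tested independently:

    simulate -> (angular CSVs | TIFF movies) -> track -> analyze -> compare

Reports carry a provenance block (config hash, seed, package version) and
no timestamps, so reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from . import io as dxt_io
from . import kinetics
from .geometry import AU111, AU200, BeamlineGeometry, default_bands
from .models import RotationalMSDModel, RotationalMSDResults, compare_results
from .synthetic import (
    ConditionModel,
    PopulationParams,
    RenderConfig,
    bgt_model,
    cch_model,
    render_movie,
    simulate_angular_trajectories,
)
from .tracking import detect_movie, filter_trajectories, link_spots
from .kinetics import to_angular

__all__ = [
    "TrackingConfig",
    "KineticsConfig",
    "RunConfig",
    "PipelineError",
    "run_condition",
    "compare_conditions",
    "track_movie",
]

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass(frozen=True)
class TrackingConfig:
    min_separation: int = 5
    threshold_k: float = 5.0
    max_displacement: float = 10.0
    min_length: int = 2
    min_ring_fraction: float = 0.8


@dataclass(frozen=True)
class KineticsConfig:
    max_lag_frames: int = 7
    fit_lag_range_ms: Tuple[float, float] = (0.1, 0.7)
    dt_ms: float = 0.7
    tail_threshold_mrad: float = 10.0
    n_bins: int = 60
    edge_lo_mrad: float = 1e-2
    edge_hi_mrad: float = 1e3
    suppression_ratio: float = 4.0
    suppression_n_se: float = 3.0

    def edges(self) -> np.ndarray:
        return kinetics.default_log_edges(self.n_bins, self.edge_lo_mrad,
                                          self.edge_hi_mrad)


@dataclass
class RunConfig:
    """Everything a run needs; constructed from YAML or defaults."""

    geometry: BeamlineGeometry = field(default_factory=BeamlineGeometry)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    kinetics: KineticsConfig = field(default_factory=KineticsConfig)
    conditions: Dict[str, ConditionModel] = field(default_factory=dict)
    seed: int = 0
    output_dir: Path = Path("dxt_run")

    def __post_init__(self) -> None:
        if not self.conditions:
            self.conditions = {"CCh": cch_model(), "BGT": bgt_model()}
        self.output_dir = Path(self.output_dir)

    # -- serialisation ----------------------------------------------------
    @classmethod
    def from_yaml(cls, path: Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        geo_raw = raw.get("geometry", {})
        geometry = BeamlineGeometry(
            peak_energy=geo_raw.get("peak_energy_keV", 15.8),
            fractional_bandwidth=geo_raw.get("fractional_bandwidth", 0.08),
            camera_length=geo_raw.get("camera_length_mm", 50.0),
            pixel_pitch=geo_raw.get("pixel_pitch_mm", 0.08),
            beam_center=tuple(geo_raw.get("beam_center_px", (255.5, 255.5))),
            detector_shape=tuple(geo_raw.get("detector_shape_px", (512, 512))),
            frame_interval=geo_raw.get("frame_interval_ms", 0.1),
        )
        tracking = TrackingConfig(**raw.get("tracking", {}))
        kin_raw = dict(raw.get("kinetics", {}))
        if "fit_lag_range_ms" in kin_raw:
            kin_raw["fit_lag_range_ms"] = tuple(kin_raw["fit_lag_range_ms"])
        kin = KineticsConfig(**kin_raw)
        conditions = {}
        for label, c in (raw.get("conditions") or {}).items():
            pops = tuple(
                PopulationParams(**p) for p in c.get("populations", [])
            ) or None
            base = {"CCh": cch_model, "BGT": bgt_model}.get(label)
            defaults = base() if base else cch_model()
            conditions[label] = ConditionModel(
                label=label,
                populations=pops if pops else defaults.populations,
                n_trajectories=c.get("n_trajectories", defaults.n_trajectories),
                ligand=c.get("ligand", defaults.ligand),
                mean_lifetime=c.get("mean_lifetime_ms", defaults.mean_lifetime),
                frame_interval=c.get("frame_interval_ms", geometry.frame_interval),
                max_duration=c.get("max_duration_ms", defaults.max_duration),
            )
        return cls(
            geometry=geometry, tracking=tracking, kinetics=kin,
            conditions=conditions,
            seed=int(raw.get("seed", 0)),
            output_dir=Path(raw.get("output_dir", "dxt_run")),
        )

    def to_dict(self) -> dict:
        d = {
            "geometry": {
                "peak_energy_keV": self.geometry.peak_energy,
                "fractional_bandwidth": self.geometry.fractional_bandwidth,
                "camera_length_mm": self.geometry.camera_length,
                "pixel_pitch_mm": self.geometry.pixel_pitch,
                "beam_center_px": list(self.geometry.beam_center),
                "detector_shape_px": list(self.geometry.detector_shape),
                "frame_interval_ms": self.geometry.frame_interval,
            },
            "tracking": asdict(self.tracking),
            "kinetics": {**asdict(self.kinetics),
                         "fit_lag_range_ms": list(self.kinetics.fit_lag_range_ms)},
            "conditions": {
                label: {
                    "ligand": m.ligand,
                    "n_trajectories": m.n_trajectories,
                    "mean_lifetime_ms": m.mean_lifetime,
                    "frame_interval_ms": m.frame_interval,
                    "max_duration_ms": m.max_duration,
                    "populations": [asdict(p) for p in m.populations],
                }
                for label, m in self.conditions.items()
            },
            "seed": self.seed,
            "output_dir": str(self.output_dir),
        }
        return d

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    def condition_seed(self, label: str) -> int:
        """Stable per-condition seed derived from the run seed and label."""
        h = hashlib.sha256(f"{self.seed}:{label}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


def _provenance(config: RunConfig) -> dict:
    return {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
    }


def track_movie(config: RunConfig, movie) -> Tuple[list, object]:
    """Detect, link and ring-filter the spots of one movie.

    Returns (kept spot trajectories with ring labels, filter stats).
    """
    tc = config.tracking
    try:
        per_frame = detect_movie(
            movie, min_separation=tc.min_separation, threshold_k=tc.threshold_k,
        )
        tracks = link_spots(per_frame, max_displacement=tc.max_displacement)
        bands = default_bands(config.geometry)
        kept, stats = filter_trajectories(
            tracks, min_length=tc.min_length, bands=bands,
            geometry=config.geometry, min_ring_fraction=tc.min_ring_fraction,
        )
    except (ValueError, RuntimeError) as exc:
        raise PipelineError("track", str(exc)) from exc
    return kept, stats


def run_condition(
    config: RunConfig,
    condition_label: str,
    mode: str = "angular",
    write_artifacts: bool = True,
) -> RotationalMSDResults:
    """Simulate (or render+track) one condition and fit its MSD model.

    ``mode="angular"`` analyses the generator's angular trajectories
    directly; ``mode="movie"`` renders a detector movie, re-detects and
    links the spots, converts them back to angles, and analyses those —
    the full end-to-end path.

    Artifacts (trajectory CSV, report JSON, MSD PNG) go under
    ``output_dir/<label>/``.  Deterministic for fixed config + seed.
    """
    if condition_label not in config.conditions:
        raise PipelineError(
            "config", f"condition {condition_label!r} not in config "
            f"(have {sorted(config.conditions)})"
        )
    model = config.conditions[condition_label]
    seed = config.condition_seed(condition_label)
    trajs = simulate_angular_trajectories(model, seed)

    if mode == "movie":
        rc = RenderConfig(geometry=config.geometry, seed=seed)
        movie, _truth = render_movie(trajs, rc, condition_label=condition_label)
        kept, _stats = track_movie(config, movie)
        try:
            trajs = [to_angular(tr, config.geometry) for tr in kept]
        except ValueError as exc:
            raise PipelineError("to_angular", str(exc)) from exc
        if not trajs:
            raise PipelineError("track", "no trajectories survived tracking")
        for tr in trajs:
            tr.condition_label = condition_label
    elif mode != "angular":
        raise PipelineError("config", f"unknown mode {mode!r}")

    try:
        msd_model = RotationalMSDModel(
            trajs, condition_label=condition_label,
            max_lag_frames=config.kinetics.max_lag_frames,
        )
        results = msd_model.fit(lag_range=config.kinetics.fit_lag_range_ms)
    except ValueError as exc:
        raise PipelineError("analyze", str(exc)) from exc

    if write_artifacts:
        outdir = config.output_dir / condition_label
        outdir.mkdir(parents=True, exist_ok=True)
        dxt_io.write_angular_csv(outdir / "angular.csv", trajs, condition_label)
        report = results.to_report_dict()
        report["provenance"] = _provenance(config)
        report["mode"] = mode
        kin = config.kinetics
        report["tail_fractions"] = {
            ax: results.tail_fraction(ax, kin.dt_ms, kin.tail_threshold_mrad)
            for ax in ("theta", "chi")
        }
        dxt_io.write_report(outdir / "report.json", report)
        edges = kin.edges()
        for ax in ("theta", "chi"):
            dist = results.displacement_distribution(ax, kin.dt_ms, edges)
            dxt_io.write_distribution_csv(outdir / f"distribution_{ax}.csv", dist)
        dmap = results.density_map(kin.dt_ms, edges, edges)
        dxt_io.write_map_csv(outdir / "density_map.csv", dmap)
        try:
            import matplotlib.pyplot as plt
            ax = results.plot_msd()
            ax.figure.savefig(outdir / "msd.png", dpi=120)
            plt.close(ax.figure)
        except Exception:  # plotting must never fail a run
            logger.exception("MSD plot failed for %s", condition_label)
    logger.info("condition %s: %d trajectories analysed (%s mode)",
                condition_label, results.n_trajectories, mode)
    return results


def compare_conditions(
    config: RunConfig,
    label_a: str,
    label_b: str,
    mode: str = "angular",
    results: Optional[Dict[str, RotationalMSDResults]] = None,
    write_artifacts: bool = True,
) -> dict:
    """Two-condition comparison report (a vs b).

    Assembles per-condition fits, slope ratios with a disjoint-interval
    suppression flag per axis, tail fractions above the configured
    threshold, the difference density map a − b, and the net difference
    mass in the 10–50 mrad χ band (the gating-motion signature).
    """
    results = results or {}
    for label in (label_a, label_b):
        if label not in results:
            results[label] = run_condition(config, label, mode=mode,
                                           write_artifacts=write_artifacts)
    ra, rb = results[label_a], results[label_b]

    kin = config.kinetics
    edges = kin.edges()
    dt = kin.dt_ms
    try:
        map_a = ra.density_map(dt=dt, theta_edges=edges, chi_edges=edges)
        map_b = rb.density_map(dt=dt, theta_edges=edges, chi_edges=edges)
        dmap = kinetics.difference_map(map_a, map_b)
    except ValueError as exc:
        raise PipelineError("compare", str(exc)) from exc

    # net difference mass in the chi in [10, 50] mrad cells (all theta)
    chi_lo = np.searchsorted(dmap.chi_edges, 10.0, side="left")
    chi_hi = np.searchsorted(dmap.chi_edges, 50.0, side="right") - 1
    net_gating_mass = float(dmap.mass[:, chi_lo:chi_hi].sum())

    report = {
        "a": ra.to_report_dict(),
        "b": rb.to_report_dict(),
        "dt_ms": dt,
        "contrast": {
            ax: compare_results(ra, rb, ax,
                                ratio_threshold=kin.suppression_ratio,
                                n_se=kin.suppression_n_se)
            for ax in ("theta", "chi")
        },
        "tail_fractions": {
            label_a: {ax: results[label_a].tail_fraction(ax, dt, kin.tail_threshold_mrad)
                      for ax in ("theta", "chi")},
            label_b: {ax: results[label_b].tail_fraction(ax, dt, kin.tail_threshold_mrad)
                      for ax in ("theta", "chi")},
        },
        "difference_map": {
            "net_mass_chi_10_50_mrad": net_gating_mass,
            "total_mass": dmap.total_mass(),
        },
        "provenance": _provenance(config),
    }

    if write_artifacts:
        outdir = config.output_dir
        outdir.mkdir(parents=True, exist_ok=True)
        dxt_io.write_report(outdir / f"compare_{label_a}_vs_{label_b}.json", report)
        dxt_io.write_map_csv(outdir / f"diffmap_{label_a}_vs_{label_b}.csv", dmap)
        try:
            import matplotlib.pyplot as plt
            from .plotting import plot_density_map
            ax = plot_density_map(dmap)
            ax.figure.savefig(outdir / f"diffmap_{label_a}_vs_{label_b}.png", dpi=120)
            plt.close(ax.figure)
        except Exception:
            logger.exception("difference-map plot failed")
    return report
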