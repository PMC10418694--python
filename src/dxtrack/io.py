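"""File I/O: multi-page TIFF movies, trajectory tables, JSON reports.

All tables are UTF-8 CSV with '.' decimal separator; floats are written
with 17 significant digits so write→read is the identity.  Movies are
16-bit grayscale multi-page TIFF.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .geometry import BeamlineGeometry
from .kinetics import AngularTrajectory, DensityMap2D, DisplacementDistribution
from .tracking import DetectorMovie, Spot, SpotTrajectory

__all__ = [
    "SchemaError",
    "write_movie",
    "read_movie",
    "spot_table",
    "write_spot_csv",
    "read_spot_csv",
    "angular_table",
    "write_angular_csv",
    "read_angular_csv",
    "write_report",
    "read_report",
    "write_map_csv",
]

_FLOAT_FMT = "%.17g"

SPOT_COLUMNS = ["trajectory_id", "frame", "t_ms", "x_px", "y_px", "intensity", "ring"]
ANGULAR_COLUMNS = ["trajectory_id", "t_ms", "theta_mrad", "chi_mrad", "ring", "condition"]


class SchemaError(ValueError):
    """A file does not conform to its documented schema."""


def _check_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing required columns: {missing}")


def write_movie(path: Path, movie: DetectorMovie) -> None:
    """Write a detector movie as 16-bit grayscale multi-page TIFF."""
    frames = np.asarray(movie.frames)
    if frames.dtype != np.uint16:
        if frames.max(initial=0) > 65535 or frames.min(initial=0) < 0:
            raise ValueError("movie intensities do not fit uint16")
        frames = frames.astype(np.uint16)
    tifffile.imwrite(str(path), frames, photometric="minisblack")


def read_movie(
    path: Path,
    geometry: Optional[BeamlineGeometry] = None,
    condition_label: str = "",
) -> DetectorMovie:
    """Read a multi-page TIFF movie; geometry defaults if not supplied."""
    frames = tifffile.imread(str(path))
    if frames.ndim == 2:
        frames = frames[None]
    geometry = geometry or BeamlineGeometry()
    return DetectorMovie(
        frames=frames,
        frame_interval=geometry.frame_interval,
        geometry=geometry,
        condition_label=condition_label,
    )


def spot_table(
    trajectories: Sequence[SpotTrajectory], frame_interval: float
) -> pd.DataFrame:
    """One row per spot: trajectory_id, frame, t_ms, x_px, y_px, intensity, ring."""
    rec = []
    for tr in trajectories:
        for s in tr.spots:
            rec.append(dict(
                trajectory_id=tr.trajectory_id, frame=s.frame_index,
                t_ms=s.frame_index * frame_interval, x_px=s.x, y_px=s.y,
                intensity=s.intensity, ring=tr.ring if tr.ring is not None else "none",
            ))
    return pd.DataFrame.from_records(rec, columns=SPOT_COLUMNS)


def write_spot_csv(
    path: Path, trajectories: Sequence[SpotTrajectory], frame_interval: float
) -> None:
    spot_table(trajectories, frame_interval).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_spot_csv(path: Path) -> List[SpotTrajectory]:
    """Read a spot trajectory table back into SpotTrajectory objects."""
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, SPOT_COLUMNS, f"spot table {path}")
    out: List[SpotTrajectory] = []
    for tid, grp in df.groupby("trajectory_id", sort=True):
        grp = grp.sort_values("frame")
        spots = [
            Spot(frame_index=int(r.frame), x=float(r.x_px), y=float(r.y_px),
                 intensity=float(r.intensity))
            for r in grp.itertuples(index=False)
        ]
        ring = grp["ring"].iloc[0]
        out.append(SpotTrajectory(
            trajectory_id=int(tid), spots=spots,
            ring=None if ring == "none" else str(ring),
        ))
    return out


def angular_table(
    trajectories: Sequence[AngularTrajectory], condition_label: str = ""
) -> pd.DataFrame:
    rec = []
    for tr in trajectories:
        label = tr.condition_label or condition_label
        for t, th, ch in zip(tr.t, tr.theta, tr.chi):
            rec.append(dict(
                trajectory_id=tr.trajectory_id, t_ms=t, theta_mrad=th,
                chi_mrad=ch, ring=tr.ring if tr.ring is not None else "none",
                condition=label,
            ))
    return pd.DataFrame.from_records(rec, columns=ANGULAR_COLUMNS)


def write_angular_csv(
    path: Path, trajectories: Sequence[AngularTrajectory], condition_label: str = ""
) -> None:
    angular_table(trajectories, condition_label).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_angular_csv(path: Path) -> List[AngularTrajectory]:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, ANGULAR_COLUMNS, f"angular table {path}")
    out: List[AngularTrajectory] = []
    for tid, grp in df.groupby("trajectory_id", sort=True):
        grp = grp.sort_values("t_ms")
        ring = grp["ring"].iloc[0]
        out.append(AngularTrajectory(
            trajectory_id=int(tid),
            t=grp["t_ms"].to_numpy(),
            theta=grp["theta_mrad"].to_numpy(),
            chi=grp["chi_mrad"].to_numpy(),
            ring=None if ring == "none" else str(ring),
            condition_label=str(grp["condition"].iloc[0]),
        ))
    return out


def write_report(path: Path, report: Dict) -> None:
    """Serialise a report dict to JSON (sorted keys, float-exact)."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonify)
        fh.write("\n")


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"cannot serialise {type(obj)}")


def read_report(path: Path) -> Dict:
    with open(path) as fh:
        return json.load(fh)


def write_map_csv(path: Path, dmap: DensityMap2D) -> None:
    """Write a 2-D density map as CSV with edge headers: first row/column
    carry the χ/θ bin lower edges."""
    df = pd.DataFrame(
        dmap.mass,
        index=pd.Index(dmap.theta_edges[:-1], name="theta_edge_mrad"),
        columns=pd.Index(dmap.chi_edges[:-1], name="chi_edge_mrad"),
    )
    df.to_csv(path, float_format=_FLOAT_FMT)


def write_distribution_csv(path: Path, dist: DisplacementDistribution) -> None:
    df = pd.DataFrame({
        "edge_lo_mrad": dist.bin_edges[:-1],
        "edge_hi_mrad": dist.bin_edges[1:],
        "mass": dist.mass,
    })
    df.attrs["underflow"] = dist.underflow
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
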