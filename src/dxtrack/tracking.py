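"""Diffraction-spot detection and frame-to-frame trajectory linking.

A Crocker–Grier-style pipeline: each frame is band-pass filtered
(difference of Gaussians), candidate spots are local maxima above a robust
noise threshold, and sub-pixel centres are intensity-weighted centroids.
Consecutive frames are linked by a minimum-cost bipartite assignment with a
birth/death penalty; there is no gap closing (memory = 0), because the
sub-millisecond track lifetimes typical of DXT make gap closing a source of
spurious long trajectories.

Linking objective
-----------------
Between two consecutive frames the assignment minimises

    Σ d²(link)  +  max_displacement² · (number of unmatched spots),

over matchings restricted to pairs with d ≤ max_displacement.  Since any
admissible link costs at most max_displacement², linking is always
preferred to leaving both ends unmatched; the penalty term makes the
otherwise-degenerate "minimum total squared displacement" objective
well-posed.  Equal-cost solutions are resolved deterministically by sorting
spots in canonical (row, col) order before assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import linear_sum_assignment
from skimage.feature import peak_local_max

from .geometry import BeamlineGeometry, RingBand, classify_ring, detector_to_polar

__all__ = [
    "Spot",
    "DetectorMovie",
    "SpotTrajectory",
    "FilterStats",
    "detect_spots",
    "detect_movie",
    "link_spots",
    "assign_ring",
    "filter_trajectories",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Spot:
    """A detected diffraction spot in one frame.

    ``x`` is the sub-pixel column coordinate, ``y`` the row coordinate.
    ``intensity`` is the summed background-subtracted signal and ``sigma``
    an RMS-width estimate in pixels.
    """

    frame_index: int
    x: float
    y: float
    intensity: float
    sigma: float = float("nan")


@dataclass
class DetectorMovie:
    """A stack of detector frames with its acquisition geometry."""

    frames: np.ndarray  # (T, rows, cols), non-negative
    frame_interval: float  # ms
    geometry: BeamlineGeometry
    condition_label: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("movie must be a (T >= 2, rows, cols) stack")
        if np.any(self.frames < 0):
            raise ValueError("movie intensities must be non-negative")
        if tuple(self.frames.shape[1:]) != tuple(self.geometry.detector_shape):
            raise ValueError(
                f"frame shape {self.frames.shape[1:]} does not match detector "
                f"{self.geometry.detector_shape}"
            )

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])


@dataclass
class SpotTrajectory:
    """Spots of one crystal linked across strictly consecutive frames.

    At the linking stage singletons (length 1) are legitimate members of
    the output — every detected spot belongs to exactly one trajectory —
    and are removed by :func:`filter_trajectories`, whose default
    ``min_length=2`` restores the analysis-level invariant.
    """

    trajectory_id: int
    spots: List[Spot]
    ring: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.spots:
            raise ValueError("trajectory must contain at least one spot")
        frames = [s.frame_index for s in self.spots]
        if any(b - a != 1 for a, b in zip(frames, frames[1:])):
            raise ValueError("frame indices must be strictly consecutive")

    def __len__(self) -> int:
        return len(self.spots)

    def duration_ms(self, frame_interval: float) -> float:
        """Exposure span of the track: n_frames · frame_interval."""
        return len(self.spots) * frame_interval


def detect_spots(
    frame: np.ndarray,
    min_separation: int = 5,
    threshold_k: float = 5.0,
    frame_index: int = 0,
    psf_sigma: float = 1.0,
) -> List[Spot]:
    """Detect diffraction spots in a single frame.

    The frame is band-pass filtered with a difference of Gaussians
    (``psf_sigma`` vs ``min_separation``), candidate pixels are local
    maxima exceeding ``median + threshold_k × robust σ`` (robust σ =
    1.4826·MAD of the filtered frame), and each spot's centre is the
    intensity-weighted centroid over a square window of radius
    ``min_separation``.  Returned spots are pairwise at least
    ``min_separation`` apart; on conflict the brighter spot wins.

    Raises
    ------
    ValueError
        If the frame contains non-finite values.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise ValueError("empty frame")
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite pixel values")

    bp = gaussian_filter(frame, psf_sigma) - gaussian_filter(frame, float(min_separation))
    med = float(np.median(bp))
    mad = float(np.median(np.abs(bp - med)))
    robust_sigma = 1.4826 * mad
    threshold = med + threshold_k * robust_sigma

    peaks = peak_local_max(
        bp,
        min_distance=int(min_separation),
        threshold_abs=threshold,
        exclude_border=False,
    )
    if peaks.size == 0:
        return []

    signal = np.clip(bp - med, 0.0, None)
    rows, cols = frame.shape
    r = int(min_separation)
    candidates: List[Spot] = []
    for py, px in peaks:
        y0, y1 = max(0, py - r), min(rows, py + r + 1)
        x0, x1 = max(0, px - r), min(cols, px + r + 1)
        win = signal[y0:y1, x0:x1]
        total = float(win.sum())
        if total <= 0:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        cy = float((yy * win).sum() / total)
        cx = float((xx * win).sum() / total)
        var = float((((yy - cy) ** 2 + (xx - cx) ** 2) * win).sum() / total)
        candidates.append(
            Spot(frame_index=frame_index, x=cx, y=cy, intensity=total,
                 sigma=float(np.sqrt(var / 2.0)))
        )

    # enforce pairwise separation, brighter spot wins
    candidates.sort(key=lambda s: (-s.intensity, s.y, s.x))
    kept: List[Spot] = []
    min_sep2 = float(min_separation) ** 2
    for c in candidates:
        if all((c.x - k.x) ** 2 + (c.y - k.y) ** 2 >= min_sep2 for k in kept):
            kept.append(c)
    kept.sort(key=lambda s: (s.y, s.x))
    return kept


def detect_movie(
    movie: DetectorMovie,
    min_separation: int = 5,
    threshold_k: float = 5.0,
    psf_sigma: float = 1.0,
) -> List[List[Spot]]:
    """Run :func:`detect_spots` on every frame of a movie."""
    out = []
    for i in range(movie.n_frames):
        spots = detect_spots(
            movie.frames[i], min_separation=min_separation,
            threshold_k=threshold_k, frame_index=i, psf_sigma=psf_sigma,
        )
        out.append(spots)
    logger.info("detected %d spots over %d frames",
                sum(len(s) for s in out), movie.n_frames)
    return out


def _link_two_frames(
    current: Sequence[Spot], nxt: Sequence[Spot], max_displacement: float
) -> List[Tuple[int, int]]:
    """Matched index pairs (i in current, j in next) under the gated
    birth/death-penalised assignment."""
    n1, n2 = len(current), len(nxt)
    if n1 == 0 or n2 == 0:
        return []
    penalty = max_displacement**2
    forbidden = 1e12
    size = n1 + n2
    cost = np.zeros((size, size))
    cost[:n1, n2:] = penalty  # spot in current -> death
    cost[n1:, :n2] = penalty  # birth -> spot in next
    for i, a in enumerate(current):
        for j, b in enumerate(nxt):
            d2 = (a.x - b.x) ** 2 + (a.y - b.y) ** 2
            cost[i, j] = d2 if d2 <= penalty else forbidden
    rows, cols = linear_sum_assignment(cost)
    return [(i, j) for i, j in zip(rows, cols) if i < n1 and j < n2 and cost[i, j] < forbidden]


def link_spots(
    per_frame_spots: Sequence[Sequence[Spot]],
    max_displacement: float = 10.0,
) -> List[SpotTrajectory]:
    """Link detected spots into trajectories across consecutive frames.

    Parameters
    ----------
    per_frame_spots : sequence of sequences of Spot
        Element ``t`` holds the spots of frame ``t`` (empty lists allowed).
    max_displacement : float
        Gating radius in pixels; candidate links farther than this are
        forbidden, and each unmatched spot pays ``max_displacement²`` in
        the assignment objective.

    Returns
    -------
    list of SpotTrajectory
        Every input spot appears in exactly one trajectory; unmatched
        spots become singletons.  No gap closing.
    """
    if not max_displacement > 0:
        raise ValueError("max_displacement must be positive")

    # canonical within-frame order makes the result invariant to input order
    frames: List[List[Spot]] = [
        sorted(frame_spots, key=lambda sp: (sp.y, sp.x, -sp.intensity))
        for frame_spots in per_frame_spots
    ]

    trajectories: List[List[Spot]] = []
    active: Dict[int, int] = {}  # spot index in current frame -> trajectory index
    for t, spots in enumerate(frames):
        if t == 0:
            for i, s in enumerate(spots):
                active[i] = len(trajectories)
                trajectories.append([s])
            continue
        prev = frames[t - 1]
        links = _link_two_frames(prev, spots, max_displacement)
        new_active: Dict[int, int] = {}
        for i, j in links:
            traj_idx = active[i]
            trajectories[traj_idx].append(spots[j])
            new_active[j] = traj_idx
        for j, s in enumerate(spots):
            if j not in new_active:
                new_active[j] = len(trajectories)
                trajectories.append([s])
        active = new_active

    out = [SpotTrajectory(trajectory_id=k, spots=sp) for k, sp in enumerate(trajectories)]
    logger.info("linked %d spots into %d trajectories",
                sum(len(t) for t in out), len(out))
    return out


def assign_ring(
    trajectory: SpotTrajectory,
    bands: Sequence[RingBand],
    geometry: BeamlineGeometry,
    min_fraction: float = 0.8,
) -> Optional[str]:
    """Majority-vote ring label of a trajectory.

    Returns the plane whose band contains the largest number of the
    trajectory's spots, provided that plane accounts for at least
    ``min_fraction`` of them; otherwise None (the trajectory is dropped
    downstream).
    """
    votes: Dict[Optional[str], int] = {}
    for s in trajectory.spots:
        polar = detector_to_polar(s.x, s.y, geometry)
        label = classify_ring(polar, bands, geometry)
        votes[label] = votes.get(label, 0) + 1
    best = max(votes, key=lambda k: (votes[k], k is not None))
    if best is None:
        return None
    if votes[best] / len(trajectory.spots) < min_fraction:
        return None
    return best


@dataclass
class FilterStats:
    """Bookkeeping from :func:`filter_trajectories` for the run log."""

    n_input: int
    n_kept: int
    n_discarded_short: int
    n_discarded_ring: int
    mean_duration_ms: float


def filter_trajectories(
    trajectories: Sequence[SpotTrajectory],
    min_length: int = 2,
    bands: Optional[Sequence[RingBand]] = None,
    geometry: Optional[BeamlineGeometry] = None,
    min_ring_fraction: float = 0.8,
) -> Tuple[List[SpotTrajectory], FilterStats]:
    """Keep trajectories long enough and assignable to a diffraction ring.

    A trajectory survives if it has at least ``min_length`` spots and (when
    ``bands`` is given) its majority ring label is not None.  Ring labels
    are written onto the kept trajectories.  Counts and the mean kept-track
    duration are logged and returned.
    """
    geometry = geometry or BeamlineGeometry()
    kept: List[SpotTrajectory] = []
    n_short = n_ring = 0
    for traj in trajectories:
        if len(traj) < min_length:
            n_short += 1
            continue
        if bands is not None:
            ring = assign_ring(traj, bands, geometry, min_fraction=min_ring_fraction)
            if ring is None:
                n_ring += 1
                continue
            traj.ring = ring
        kept.append(traj)
    mean_ms = (
        float(np.mean([t.duration_ms(geometry.frame_interval) for t in kept]))
        if kept else 0.0
    )
    stats = FilterStats(
        n_input=len(trajectories),
        n_kept=len(kept),
        n_discarded_short=n_short,
        n_discarded_ring=n_ring,
        mean_duration_ms=mean_ms,
    )
    logger.info(
        "filter: kept %d / %d trajectories (%d too short, %d off-ring); "
        "mean duration %.3f ms",
        stats.n_kept, stats.n_input, n_short, n_ring, mean_ms,
    )
    return kept, stats
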