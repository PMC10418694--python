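"""Angular trajectories and rotational-motion statistics.

This is the analysis core of the package: spot trajectories become angular
trajectories — time series of crystal tilt (θ) and twist (χ) in mrad
relative to the first observed frame — and the ensemble of angular
trajectories yields the headline statistics of a DXT experiment:

* per-axis ensemble mean-square-displacement (MSD) curves with a weighted
  linear fit, whose slope estimates twice the rotational diffusion
  coefficient (MSD = 2σ² + 2DΔt for free axial rotation observed with
  static noise of variance σ²);
* distributions of |angular displacement| at a fixed lag Δt;
* two-dimensional (|Δθ|, |Δχ|) probability-density maps and their
  between-condition difference maps, which localise the motion population
  an antagonist suppresses.

The MSD estimator pools *all* ordered sample pairs (i, i+k) within each
trajectory across the whole ensemble (time-and-ensemble average); the pair
count per lag is retained and used as the weight in the linear fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import statsmodels.api as sm

from .geometry import BeamlineGeometry, angular_displacement, detector_to_polar
from .tracking import SpotTrajectory

__all__ = [
    "AngularTrajectory",
    "MSDCurve",
    "MSDFit",
    "DisplacementDistribution",
    "DensityMap2D",
    "to_angular",
    "ensemble_msd",
    "fit_msd_linear",
    "fit_msd_cluster",
    "pooled_displacements",
    "displacement_distribution",
    "tail_fraction",
    "density_map_2d",
    "difference_map",
    "default_log_edges",
    "mean_track_ms",
]

_AXES = ("theta", "chi")


@dataclass
class AngularTrajectory:
    """Tilt/twist time series of one crystal, zeroed at its first frame.

    ``t`` is in ms with uniform spacing (the frame interval); ``theta`` and
    ``chi`` are in mrad relative to the first sample, so the first sample
    is (0, 0, 0) by construction.
    """

    trajectory_id: int
    t: np.ndarray
    theta: np.ndarray
    chi: np.ndarray
    ring: Optional[str] = None
    condition_label: str = ""

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.chi = np.asarray(self.chi, dtype=float)
        n = len(self.t)
        if n < 2:
            raise ValueError("angular trajectory needs at least 2 samples")
        if not (len(self.theta) == len(self.chi) == n):
            raise ValueError("t, theta, chi must have equal length")
        steps = np.diff(self.t)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
            raise ValueError("t must increase in uniform steps")
        if abs(self.t[0]) > 1e-12 or abs(self.theta[0]) > 1e-9 or abs(self.chi[0]) > 1e-9:
            raise ValueError("first sample must be (t=0, theta=0, chi=0)")

    def axis(self, name: str) -> np.ndarray:
        if name not in _AXES:
            raise ValueError(f"axis must be one of {_AXES}, got {name!r}")
        return self.theta if name == "theta" else self.chi

    @property
    def frame_interval(self) -> float:
        return float(self.t[1] - self.t[0])

    @property
    def duration_ms(self) -> float:
        """Exposure span, n_frames · frame_interval."""
        return len(self.t) * self.frame_interval


def to_angular(
    trajectory: SpotTrajectory,
    geometry: BeamlineGeometry,
) -> AngularTrajectory:
    """Convert a linked spot trajectory to tilt/twist angles.

    Each sample's (θ, χ) is the crystal rotation from the trajectory's
    first spot: tilt is half the change in scattering angle, twist the
    wrapped azimuth change.  Time is measured from the first frame in
    units of the geometry's frame interval.

    Raises
    ------
    ValueError
        If the trajectory has no ring label (unclassified trajectories are
        excluded from kinetic analysis).
    """
    if trajectory.ring is None:
        raise ValueError(
            f"trajectory {trajectory.trajectory_id} has no ring label; "
            "run filter_trajectories with ring bands first"
        )
    first = trajectory.spots[0]
    p0 = detector_to_polar(first.x, first.y, geometry)
    t = np.empty(len(trajectory.spots))
    theta = np.empty_like(t)
    chi = np.empty_like(t)
    for i, s in enumerate(trajectory.spots):
        p = detector_to_polar(s.x, s.y, geometry)
        dth, dch = angular_displacement(p0, p)
        t[i] = (s.frame_index - first.frame_index) * geometry.frame_interval
        theta[i] = dth
        chi[i] = dch
    return AngularTrajectory(
        trajectory_id=trajectory.trajectory_id, t=t, theta=theta, chi=chi,
        ring=trajectory.ring,
    )


@dataclass
class MSDCurve:
    """Ensemble MSD versus lag for one axis, with per-lag pair counts."""

    axis: str
    lags: np.ndarray  # ms
    msd: np.ndarray  # mrad^2
    n_pairs: np.ndarray  # pooled displacement pairs per lag
    condition_label: str = ""

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_pairs = np.asarray(self.n_pairs, dtype=int)
        if np.any(self.msd < 0) or np.any(self.lags <= 0):
            raise ValueError("lags must be positive and msd non-negative")
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")


def _frame_interval_of(trajectories: Sequence[AngularTrajectory]) -> float:
    taus = {round(tr.frame_interval, 12) for tr in trajectories}
    if len(taus) != 1:
        raise ValueError(f"trajectories have mixed frame intervals: {sorted(taus)}")
    return taus.pop()


def ensemble_msd(
    trajectories: Sequence[AngularTrajectory],
    axis: str,
    max_lag_frames: int = 7,
    condition_label: str = "",
) -> MSDCurve:
    """Time-and-ensemble-averaged MSD over pooled in-trajectory pairs.

    MSD(kτ) is the mean of (x[i+k] − x[i])² over all ordered pairs of
    samples k frames apart, pooled across all trajectories.  Lags with no
    contributing pair are omitted.

    Raises
    ------
    ValueError
        If no trajectories are given.
    """
    if not trajectories:
        raise ValueError("ensemble_msd requires at least one trajectory")
    tau = _frame_interval_of(trajectories)
    sums = np.zeros(max_lag_frames)
    counts = np.zeros(max_lag_frames, dtype=int)
    for tr in trajectories:
        x = tr.axis(axis)
        n = len(x)
        for k in range(1, min(max_lag_frames, n - 1) + 1):
            d = x[k:] - x[:-k]
            sums[k - 1] += float(np.dot(d, d))
            counts[k - 1] += d.size
    keep = counts > 0
    ks = np.arange(1, max_lag_frames + 1)[keep]
    return MSDCurve(
        axis=axis,
        lags=ks * tau,
        msd=sums[keep] / counts[keep],
        n_pairs=counts[keep],
        condition_label=condition_label,
    )


@dataclass
class MSDFit:
    """Weighted linear fit MSD = intercept + slope·Δt.

    For simple rotational diffusion observed with static noise the slope
    estimates 2D (mrad²/ms) and the intercept 2σ²_noise (mrad²).
    """

    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    lag_range: Tuple[float, float]
    axis: str
    condition_label: str = ""
    n_lags: int = 0

    def __post_init__(self) -> None:
        if self.slope_se < 0 or self.intercept_se < 0:
            raise ValueError("standard errors must be non-negative")

    @property
    def diffusion_coefficient(self) -> float:
        """D = slope / 2, mrad²/ms."""
        return self.slope / 2.0

    @property
    def noise_variance(self) -> float:
        """σ²_noise = intercept / 2, mrad²."""
        return self.intercept / 2.0


def fit_msd_linear(
    curve: MSDCurve,
    lag_range: Tuple[float, float] = (0.1, 0.7),
) -> MSDFit:
    """Weighted least-squares line through an MSD curve.

    Weights are proportional to the pooled pair count at each lag;
    standard errors come from the weighted-fit covariance scaled by the
    residual variance (so an exactly linear curve has zero SEs).

    Raises
    ------
    ValueError
        If fewer than two lags fall inside ``lag_range``.
    """
    lo, hi = lag_range
    eps = 1e-9
    mask = (curve.lags >= lo - eps) & (curve.lags <= hi + eps)
    if mask.sum() < 2:
        raise ValueError(
            f"need >= 2 lags in range [{lo}, {hi}] ms, have {int(mask.sum())}"
        )
    x = curve.lags[mask]
    y = curve.msd[mask]
    w = curve.n_pairs[mask].astype(float)
    X = sm.add_constant(x)
    res = sm.WLS(y, X, weights=w).fit()
    intercept, slope = res.params
    intercept_se, slope_se = res.bse
    if mask.sum() == 2:  # saturated fit: zero residual dof, SEs undefined -> 0
        slope_se = intercept_se = 0.0
    return MSDFit(
        slope=float(slope),
        slope_se=float(np.nan_to_num(slope_se)),
        intercept=float(intercept),
        intercept_se=float(np.nan_to_num(intercept_se)),
        lag_range=(lo, hi),
        axis=curve.axis,
        condition_label=curve.condition_label,
        n_lags=int(mask.sum()),
    )


def fit_msd_cluster(
    trajectories: Sequence[AngularTrajectory],
    axis: str,
    lag_range: Tuple[float, float] = (0.1, 0.7),
    max_lag_frames: int = 7,
    condition_label: str = "",
) -> MSDFit:
    """MSD line fit with trajectory-clustered (sandwich) standard errors.

    The pair-count-weighted fit of the ensemble MSD curve is numerically
    identical to an ordinary least-squares fit of the individual squared
    pair displacements on lag (the regressor is constant within a lag), so
    this routine fits at the pair level and takes the covariance clustered
    by trajectory.  Pairs that share a trajectory are strongly dependent —
    they overlap in time and share the same diffusion path — which makes
    the curve-level weighted-LSQ standard errors of :func:`fit_msd_linear`
    several-fold too small as estimates of the sampling error; the
    clustered SEs are the ones to use when comparing a fit against ground
    truth or between conditions.

    Returns an :class:`MSDFit` whose slope/intercept equal those of
    :func:`fit_msd_linear` on the same lags, with clustered SEs.
    """
    if not trajectories:
        raise ValueError("fit_msd_cluster requires at least one trajectory")
    tau = _frame_interval_of(trajectories)
    lo, hi = lag_range
    eps = 1e-9
    ys, xs, gs = [], [], []
    for gid, tr in enumerate(trajectories):
        x = tr.axis(axis)
        for k in range(1, min(max_lag_frames, len(x) - 1) + 1):
            lag = k * tau
            if lo - eps <= lag <= hi + eps:
                d = x[k:] - x[:-k]
                ys.append(d * d)
                xs.append(np.full(d.size, lag))
                gs.append(np.full(d.size, gid))
    if not ys or len({x[0] for x in xs}) < 2:
        raise ValueError(f"need >= 2 lags in range [{lo}, {hi}] ms")
    y = np.concatenate(ys)
    X = sm.add_constant(np.concatenate(xs))
    groups = np.concatenate(gs)
    res = sm.OLS(y, X).fit(cov_type="cluster", cov_kwds={"groups": groups})
    return MSDFit(
        slope=float(res.params[1]),
        slope_se=float(res.bse[1]),
        intercept=float(res.params[0]),
        intercept_se=float(res.bse[0]),
        lag_range=(lo, hi),
        axis=axis,
        condition_label=condition_label,
        n_lags=len({float(x[0]) for x in xs}),
    )


def _lag_frames(dt: float, tau: float) -> int:
    k = dt / tau
    if abs(k - round(k)) > 1e-6 or round(k) < 1:
        raise ValueError(
            f"dt = {dt} ms is not a positive integer multiple of the "
            f"frame interval {tau} ms"
        )
    return int(round(k))


def pooled_displacements(
    trajectories: Sequence[AngularTrajectory],
    axis: str,
    dt: float,
) -> np.ndarray:
    """All in-trajectory axis displacements at lag ``dt``, pooled (signed)."""
    if not trajectories:
        raise ValueError("no trajectories")
    tau = _frame_interval_of(trajectories)
    k = _lag_frames(dt, tau)
    parts = []
    for tr in trajectories:
        x = tr.axis(axis)
        if len(x) > k:
            parts.append(x[k:] - x[:-k])
    if not parts:
        raise ValueError(f"no displacement pairs at dt = {dt} ms")
    return np.concatenate(parts)


def default_log_edges(
    n_bins: int = 60, lo: float = 1e-2, hi: float = 1e3
) -> np.ndarray:
    """Log-spaced |displacement| bin edges in mrad (default 60 bins over
    [0.01, 1000] mrad, matching the decades DXT displacements span)."""
    return np.logspace(np.log10(lo), np.log10(hi), n_bins + 1)


@dataclass
class DisplacementDistribution:
    """Probability mass of |displacement| at fixed lag on log-spaced bins.

    ``underflow``/``overflow`` hold the mass below/above the edge span, so
    the masses always total exactly 1.
    """

    axis: str
    dt: float
    bin_edges: np.ndarray
    mass: np.ndarray
    underflow: float
    overflow: float
    n_pairs: int = 0
    condition_label: str = ""

    def total_mass(self) -> float:
        return float(self.mass.sum() + self.underflow + self.overflow)


def displacement_distribution(
    trajectories: Sequence[AngularTrajectory],
    axis: str,
    dt: float = 0.7,
    edges: Optional[np.ndarray] = None,
    condition_label: str = "",
) -> DisplacementDistribution:
    """Normalised histogram of |axis displacement| at lag ``dt``."""
    edges = default_log_edges() if edges is None else np.asarray(edges, dtype=float)
    d = np.abs(pooled_displacements(trajectories, axis, dt))
    counts, _ = np.histogram(d, bins=edges)
    n = d.size
    under = float(np.count_nonzero(d < edges[0])) / n
    over = float(np.count_nonzero(d > edges[-1])) / n
    return DisplacementDistribution(
        axis=axis, dt=dt, bin_edges=edges, mass=counts / n,
        underflow=under, overflow=over, n_pairs=n,
        condition_label=condition_label,
    )


def tail_fraction(
    trajectories: Sequence[AngularTrajectory],
    axis: str,
    dt: float = 0.7,
    threshold: float = 10.0,
) -> float:
    """Fraction of pooled |displacements| at lag ``dt`` strictly above
    ``threshold`` mrad.

    The 10 mrad default marks the motion amplitude whose suppression by an
    antagonist distinguishes gating-related twist from baseline wobble.
    """
    d = np.abs(pooled_displacements(trajectories, axis, dt))
    return float(np.count_nonzero(d > threshold)) / d.size


@dataclass
class DensityMap2D:
    """Joint probability mass of (|Δθ|, |Δχ|) at fixed lag.

    A single-condition map sums to 1 over its cells (pairs falling outside
    the edge span are excluded from the normalisation); a difference map
    sums to 0.
    """

    dt: float
    theta_edges: np.ndarray
    chi_edges: np.ndarray
    mass: np.ndarray  # (n_theta_bins, n_chi_bins)
    condition_label: str = ""
    is_difference: bool = False

    def total_mass(self) -> float:
        return float(self.mass.sum())


def density_map_2d(
    trajectories: Sequence[AngularTrajectory],
    dt: float = 0.7,
    theta_edges: Optional[np.ndarray] = None,
    chi_edges: Optional[np.ndarray] = None,
    condition_label: str = "",
) -> DensityMap2D:
    """Joint histogram of (|Δθ|, |Δχ|) pairs at lag ``dt`` on log-spaced
    edges, normalised to unit total mass."""
    theta_edges = default_log_edges() if theta_edges is None else np.asarray(theta_edges, float)
    chi_edges = default_log_edges() if chi_edges is None else np.asarray(chi_edges, float)
    dth = np.abs(pooled_displacements(trajectories, "theta", dt))
    dch = np.abs(pooled_displacements(trajectories, "chi", dt))
    counts, _, _ = np.histogram2d(dth, dch, bins=(theta_edges, chi_edges))
    total = counts.sum()
    if total == 0:
        raise ValueError("no displacement pairs fall inside the map edges")
    return DensityMap2D(
        dt=dt, theta_edges=theta_edges, chi_edges=chi_edges,
        mass=counts / total, condition_label=condition_label,
    )


def difference_map(map_a: DensityMap2D, map_b: DensityMap2D) -> DensityMap2D:
    """Cell-wise ``map_a − map_b``; positive cells mark motion enriched in
    condition a.  Requires identical binning and lag."""
    if map_a.dt != map_b.dt:
        raise ValueError(f"lag mismatch: {map_a.dt} vs {map_b.dt} ms")
    if (map_a.theta_edges.shape != map_b.theta_edges.shape
            or map_a.chi_edges.shape != map_b.chi_edges.shape
            or not np.allclose(map_a.theta_edges, map_b.theta_edges)
            or not np.allclose(map_a.chi_edges, map_b.chi_edges)):
        raise ValueError("difference map requires identical bin edges")
    return DensityMap2D(
        dt=map_a.dt,
        theta_edges=map_a.theta_edges,
        chi_edges=map_a.chi_edges,
        mass=map_a.mass - map_b.mass,
        condition_label=f"{map_a.condition_label}-{map_b.condition_label}",
        is_difference=True,
    )


def mean_track_ms(trajectories: Sequence[AngularTrajectory]) -> float:
    """Mean exposure span of the trajectories, ms."""
    if not trajectories:
        raise ValueError("no trajectories")
    return float(np.mean([tr.duration_ms for tr in trajectories]))
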