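"""Model/results objects for ensemble rotational-diffusion analysis.

`RotationalMSDModel` is the front door of the package: build it from a
list of angular trajectories (or a tidy DataFrame), call :meth:`fit`, and
read the per-axis diffusion coefficients, noise variances and their
standard errors off the returned :class:`RotationalMSDResults`, whose
``summary()`` prints a fit table.  Displacement distributions, tail
fractions, density maps and plots hang off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import kinetics
from .kinetics import (
    AngularTrajectory,
    DensityMap2D,
    DisplacementDistribution,
    MSDCurve,
    MSDFit,
)

__all__ = ["RotationalMSDModel", "RotationalMSDResults", "compare_results"]

_AXES = ("theta", "chi")


class RotationalMSDModel:
    """Ensemble MSD model of tilt/twist rotational diffusion.

    The model asserts MSD_axis(Δt) = 2σ²_axis + 2D_axis·Δt for each axis
    and estimates (D, σ²) per axis by a pair-count-weighted linear fit of
    the pooled ensemble MSD.

    Parameters
    ----------
    trajectories : sequence of AngularTrajectory
        The ensemble; all trajectories must share one frame interval.
    condition_label : str, optional
        Label carried into curves, fits and reports (defaults to the
        trajectories' own label when uniform).
    max_lag_frames : int
        Number of MSD lags computed (default 7, i.e. 0.1–0.7 ms at the
        default 0.1 ms frame interval — the mean trackable span).
    """

    def __init__(
        self,
        trajectories: Sequence[AngularTrajectory],
        condition_label: Optional[str] = None,
        max_lag_frames: int = 7,
    ) -> None:
        if not trajectories:
            raise ValueError("model requires at least one trajectory")
        self.trajectories: List[AngularTrajectory] = list(trajectories)
        if condition_label is None:
            labels = {tr.condition_label for tr in trajectories}
            condition_label = labels.pop() if len(labels) == 1 else ""
        self.condition_label = condition_label
        self.max_lag_frames = int(max_lag_frames)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        condition_label: Optional[str] = None,
        max_lag_frames: int = 7,
    ) -> "RotationalMSDModel":
        """Build from a tidy table with columns ``trajectory_id``,
        ``t_ms``, ``theta_mrad``, ``chi_mrad`` (and optionally ``ring``,
        ``condition``)."""
        required = ["trajectory_id", "t_ms", "theta_mrad", "chi_mrad"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        trajs = []
        for tid, grp in df.groupby("trajectory_id", sort=True):
            grp = grp.sort_values("t_ms")
            ring = str(grp["ring"].iloc[0]) if "ring" in grp else None
            label = str(grp["condition"].iloc[0]) if "condition" in grp else ""
            trajs.append(AngularTrajectory(
                trajectory_id=int(tid),
                t=grp["t_ms"].to_numpy(),
                theta=grp["theta_mrad"].to_numpy(),
                chi=grp["chi_mrad"].to_numpy(),
                ring=None if ring in (None, "none") else ring,
                condition_label=label,
            ))
        return cls(trajs, condition_label=condition_label,
                   max_lag_frames=max_lag_frames)

    def msd_curve(self, axis: str) -> MSDCurve:
        return kinetics.ensemble_msd(
            self.trajectories, axis, self.max_lag_frames,
            condition_label=self.condition_label,
        )

    def fit(
        self,
        lag_range: Tuple[float, float] = (0.1, 0.7),
        cov_type: str = "nonrobust",
    ) -> "RotationalMSDResults":
        """Fit the per-axis weighted MSD lines and return the results.

        ``cov_type="nonrobust"`` (default) reports the weighted-LSQ
        standard errors of the curve fit — the convention DXT studies
        print.  ``cov_type="cluster"`` reports trajectory-clustered SEs,
        which account for the strong dependence between overlapping pairs
        of the same trajectory and are the ones to use for inference
        (point estimates are identical).
        """
        if cov_type not in ("nonrobust", "cluster"):
            raise ValueError(f"cov_type must be 'nonrobust' or 'cluster', got {cov_type!r}")
        curves = {ax: self.msd_curve(ax) for ax in _AXES}
        if cov_type == "nonrobust":
            fits = {ax: kinetics.fit_msd_linear(curves[ax], lag_range) for ax in _AXES}
        else:
            fits = {
                ax: kinetics.fit_msd_cluster(
                    self.trajectories, ax, lag_range, self.max_lag_frames,
                    condition_label=self.condition_label,
                )
                for ax in _AXES
            }
        return RotationalMSDResults(self, curves, fits, cov_type=cov_type)


@dataclass
class RotationalMSDResults:
    """Fitted ensemble rotational-diffusion parameters for one condition."""

    model: RotationalMSDModel
    curves: Dict[str, MSDCurve]
    fits: Dict[str, MSDFit]
    cov_type: str = "nonrobust"

    @property
    def condition_label(self) -> str:
        return self.model.condition_label

    def cluster_fit(self, axis: str) -> MSDFit:
        """The same line with trajectory-clustered SEs (cached)."""
        if not hasattr(self, "_cluster_fits"):
            self._cluster_fits: Dict[str, MSDFit] = {}
        if axis not in self._cluster_fits:
            if self.cov_type == "cluster":
                self._cluster_fits[axis] = self.fits[axis]
            else:
                self._cluster_fits[axis] = kinetics.fit_msd_cluster(
                    self.model.trajectories, axis,
                    self.fits[axis].lag_range, self.model.max_lag_frames,
                    condition_label=self.condition_label,
                )
        return self._cluster_fits[axis]

    @property
    def n_trajectories(self) -> int:
        return len(self.model.trajectories)

    @property
    def mean_track_ms(self) -> float:
        return kinetics.mean_track_ms(self.model.trajectories)

    @property
    def params(self) -> pd.DataFrame:
        """Slope/intercept (± SE) per axis, plus derived D and σ²."""
        rows = {}
        for ax, fit in self.fits.items():
            rows[ax] = dict(
                slope=fit.slope, slope_se=fit.slope_se,
                intercept=fit.intercept, intercept_se=fit.intercept_se,
                D=fit.diffusion_coefficient, sigma2=fit.noise_variance,
            )
        return pd.DataFrame.from_dict(rows, orient="index")

    def diffusion_coefficient(self, axis: str) -> float:
        return self.fits[axis].diffusion_coefficient

    def noise_variance(self, axis: str) -> float:
        return self.fits[axis].noise_variance

    def displacement_distribution(
        self, axis: str, dt: float = 0.7, edges: Optional[np.ndarray] = None
    ) -> DisplacementDistribution:
        return kinetics.displacement_distribution(
            self.model.trajectories, axis, dt, edges,
            condition_label=self.condition_label,
        )

    def tail_fraction(self, axis: str, dt: float = 0.7, threshold: float = 10.0) -> float:
        return kinetics.tail_fraction(self.model.trajectories, axis, dt, threshold)

    def density_map(
        self,
        dt: float = 0.7,
        theta_edges: Optional[np.ndarray] = None,
        chi_edges: Optional[np.ndarray] = None,
    ) -> DensityMap2D:
        return kinetics.density_map_2d(
            self.model.trajectories, dt, theta_edges, chi_edges,
            condition_label=self.condition_label,
        )

    def plot_msd(self, ax=None):
        from .plotting import plot_msd
        return plot_msd(self, ax=ax)

    def summary(self) -> str:
        """Statsmodels-style text table of the fit."""
        lab = self.condition_label or "(unlabelled)"
        lines = [
            "Ensemble rotational MSD fit",
            "=" * 64,
            f"Condition:        {lab}",
            f"Trajectories:     {self.n_trajectories}",
            f"Mean track span:  {self.mean_track_ms:.3f} ms",
            f"Fit lag range:    {self.fits['theta'].lag_range[0]:.1f}-"
            f"{self.fits['theta'].lag_range[1]:.1f} ms "
            f"({self.fits['theta'].n_lags} lags, pair-count weighted)",
            "-" * 64,
            f"{'axis':<6}{'slope':>10}{'(SE)':>9}{'intercept':>12}{'(SE)':>9}"
            f"{'D':>9}{'sigma^2':>9}",
            f"{'':<6}{'mrad^2/ms':>10}{'':>9}{'mrad^2':>12}{'':>9}"
            f"{'mrad^2/ms':>9}{'mrad^2':>9}",
            "-" * 64,
        ]
        for ax_name in _AXES:
            f = self.fits[ax_name]
            lines.append(
                f"{ax_name:<6}{f.slope:>10.3f}{f.slope_se:>9.3f}"
                f"{f.intercept:>12.3f}{f.intercept_se:>9.3f}"
                f"{f.diffusion_coefficient:>9.3f}{f.noise_variance:>9.3f}"
            )
        lines.append("=" * 64)
        return "\n".join(lines)

    def to_report_dict(self) -> dict:
        """JSON-serialisable fit report for this condition."""
        out = {
            "condition": self.condition_label,
            "n_trajectories": self.n_trajectories,
            "mean_track_ms": self.mean_track_ms,
            "axes": {},
        }
        for ax, fit in self.fits.items():
            curve = self.curves[ax]
            cfit = self.cluster_fit(ax)
            out["axes"][ax] = {
                "slope": fit.slope,
                "slope_se": fit.slope_se,
                "intercept": fit.intercept,
                "intercept_se": fit.intercept_se,
                "slope_se_cluster": cfit.slope_se,
                "intercept_se_cluster": cfit.intercept_se,
                "lag_range_ms": list(fit.lag_range),
                "lags_ms": curve.lags.tolist(),
                "msd_mrad2": curve.msd.tolist(),
                "n_pairs_per_lag": curve.n_pairs.tolist(),
            }
        return out


def compare_results(
    a: RotationalMSDResults,
    b: RotationalMSDResults,
    axis: str,
    ratio_threshold: float = 4.0,
    n_se: float = 3.0,
) -> dict:
    """Slope contrast between two fitted conditions on one axis.

    Uncertainty comes from the trajectory-clustered SEs (see
    :func:`dxtrack.kinetics.fit_msd_cluster`); the curve-level weighted
    SEs understate the sampling error and would routinely declare
    spurious differences.  The suppression call combines a slope ratio
    above ``ratio_threshold`` with a significant slope difference,
    |Δslope| > n_se·√(SE_a² + SE_b²); the more conservative
    disjoint-interval check at the same ``n_se`` is also reported.
    """
    fa, fb = a.cluster_fit(axis), b.cluster_fit(axis)
    lo_a, hi_a = fa.slope - n_se * fa.slope_se, fa.slope + n_se * fa.slope_se
    lo_b, hi_b = fb.slope - n_se * fb.slope_se, fb.slope + n_se * fb.slope_se
    disjoint = lo_a > hi_b or lo_b > hi_a
    se_diff = np.hypot(fa.slope_se, fb.slope_se)
    significant = abs(fa.slope - fb.slope) > n_se * se_diff
    ratio = fa.slope / fb.slope if fb.slope != 0 else float("inf")
    return {
        "axis": axis,
        "slope_a": fa.slope,
        "slope_se_a": fa.slope_se,
        "slope_b": fb.slope,
        "slope_se_b": fb.slope_se,
        "ratio": ratio,
        "significant": bool(significant),
        "intervals_disjoint": bool(disjoint),
        "suppressed": bool(significant and ratio > ratio_threshold),
    }
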