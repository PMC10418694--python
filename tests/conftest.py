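"""Shared fixtures and trajectory builders."""

from __future__ import annotations

import math

import numpy as np
import pytest

from dxtrack.geometry import BeamlineGeometry, default_bands, polar_to_detector
from dxtrack.kinetics import AngularTrajectory
from dxtrack.tracking import Spot, SpotTrajectory


@pytest.fixture(scope="session")
def geometry() -> BeamlineGeometry:
    return BeamlineGeometry()


@pytest.fixture(scope="session")
def bands(geometry):
    return default_bands(geometry)


def drift_trajectory(
    v_theta: float, v_chi: float, n: int, tau: float = 0.1, tid: int = 0
) -> AngularTrajectory:
    """Deterministic linear drift: theta_k = v_theta*k, chi_k = v_chi*k (mrad)."""
    k = np.arange(n)
    return AngularTrajectory(
        trajectory_id=tid, t=k * tau, theta=v_theta * k, chi=v_chi * k
    )


def random_trajectories(
    rng: np.random.Generator, n_traj: int, scale: float = 3.0, tau: float = 0.1
) -> list[AngularTrajectory]:
    """Short random-walk trajectories for oracle comparisons."""
    out = []
    for i in range(n_traj):
        n = int(rng.integers(2, 12))
        th = np.concatenate([[0.0], np.cumsum(rng.normal(0, scale, n - 1))])
        ch = np.concatenate([[0.0], np.cumsum(rng.normal(0, scale, n - 1))])
        out.append(AngularTrajectory(trajectory_id=i, t=np.arange(n) * tau,
                                     theta=th, chi=ch))
    return out


def spot_trajectory_from_polar(
    polar_points, geometry: BeamlineGeometry, ring: str = "Au111",
    tid: int = 0, first_frame: int = 0,
) -> SpotTrajectory:
    """Build a SpotTrajectory whose spots sit at given (two_theta, chi)."""
    spots = []
    for j, (tt, ch) in enumerate(polar_points):
        x, y = polar_to_detector(tt, ch, geometry)
        spots.append(Spot(frame_index=first_frame + j, x=x, y=y, intensity=1.0))
    return SpotTrajectory(trajectory_id=tid, spots=spots, ring=ring)
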