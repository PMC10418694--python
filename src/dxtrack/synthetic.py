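"""Generative models for DXT angular trajectories and rendered movies.

The raw single-molecule data this analysis was designed for are not
publicly deposited, so the package carries a calibrated generator whose
default condition models reproduce the published ensemble MSD parameters
of nicotinic acetylcholine receptors labelled on the α-subunit:

* an agonist condition ("CCh", carbamylcholine 2 µM) with free twist
  rotation, and
* an antagonist condition ("BGT", α-bungarotoxin 0.2 µM) in which twist
  (χ) is strongly suppressed while tilt (θ) is nearly unchanged.

The generative law per trajectory is the minimal model consistent with a
linear MSD with a positive intercept: each axis performs independent
Brownian rotation with diffusion coefficient D (per-step variance 2Dτ),
observed through i.i.d. Gaussian static noise of SD σ, so the ensemble MSD
is 2σ² + 2DΔt.  Track lifetimes are geometric (memoryless per-frame
termination) with a mean of 0.7 ms, clipped to [2, 100] frames.

Calibration of the defaults (slope = 2D, intercept = 2σ²):

=========  =========  ==========  ===========  ===========
condition  D_θ        D_χ         σ²_θ         σ²_χ
           mrad²/ms   mrad²/ms    mrad²        mrad²
=========  =========  ==========  ===========  ===========
CCh        10.35      9.225       3.5715       7.398
BGT        7.385      1.1555      2.5735       3.103
=========  =========  ==========  ===========  ===========

Seeding is hierarchical (condition → trajectory → frame) off a single
integer seed via numpy ``SeedSequence``, so any subset of a dataset is
reproducible in isolation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .geometry import (
    AU111,
    AU200,
    BeamlineGeometry,
    CrystalPlane,
    bragg_angle,
    ring_band,
    wavelength,
)
from .kinetics import AngularTrajectory
from .tracking import DetectorMovie

__all__ = [
    "PopulationParams",
    "ConditionModel",
    "RenderConfig",
    "cch_model",
    "bgt_model",
    "default_condition_models",
    "simulate_angular_trajectories",
    "render_movie",
    "make_dataset",
]


@dataclass(frozen=True)
class PopulationParams:
    """One sub-population's motion parameters.

    D's are rotational diffusion coefficients in mrad²/ms; σ's are static
    measurement-noise SDs in mrad.
    """

    weight: float
    D_theta: float
    D_chi: float
    sigma_theta: float
    sigma_chi: float

    def __post_init__(self) -> None:
        if not 0 <= self.weight <= 1:
            raise ValueError("weight must be in [0, 1]")
        for v, name in ((self.D_theta, "D_theta"), (self.D_chi, "D_chi"),
                        (self.sigma_theta, "sigma_theta"), (self.sigma_chi, "sigma_chi")):
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")


@dataclass(frozen=True)
class ConditionModel:
    """Generative parameters for one ligand condition."""

    label: str
    populations: Tuple[PopulationParams, ...]
    n_trajectories: int
    ligand: str = ""
    mean_lifetime: float = 0.7  # ms
    frame_interval: float = 0.1  # ms
    max_duration: float = 10.0  # ms (record length)

    def __post_init__(self) -> None:
        if self.n_trajectories < 1:
            raise ValueError("n_trajectories must be >= 1")
        if not 0 < self.mean_lifetime <= self.max_duration:
            raise ValueError("require 0 < mean_lifetime <= max_duration")
        n_frames = self.max_duration / self.frame_interval
        if abs(n_frames - round(n_frames)) > 1e-9:
            raise ValueError("frame_interval must divide max_duration")
        total_w = sum(p.weight for p in self.populations)
        if not math.isclose(total_w, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"population weights must sum to 1, got {total_w}")

    @property
    def max_frames(self) -> int:
        return int(round(self.max_duration / self.frame_interval))


def cch_model(two_population: bool = False) -> ConditionModel:
    """Default agonist (carbamylcholine, 2 µM) condition model.

    With ``two_population=True`` the twist motion is split into a baseline
    population (χ diffusion as slow as the antagonist condition) plus a
    30%-weight gating population whose D_χ is raised so that the ensemble
    χ slope is preserved: w·D_gate + (1−w)·D_base = D_ensemble.  This
    variant produces the heavy χ tail concentrated in a minority of
    molecules rather than spread over all of them.
    """
    D_theta, D_chi = 10.35, 9.225
    s2_theta, s2_chi = 3.5715, 7.398
    st, sc = math.sqrt(s2_theta), math.sqrt(s2_chi)
    if not two_population:
        pops = (PopulationParams(1.0, D_theta, D_chi, st, sc),)
    else:
        w_gate = 0.3
        D_chi_base = 1.1555  # antagonist-like baseline twist
        D_chi_gate = (D_chi - (1 - w_gate) * D_chi_base) / w_gate
        pops = (
            PopulationParams(1 - w_gate, D_theta, D_chi_base, st, sc),
            PopulationParams(w_gate, D_theta, D_chi_gate, st, sc),
        )
    return ConditionModel(
        label="CCh", populations=pops, n_trajectories=157,
        ligand="carbamylcholine 2 uM",
    )


def bgt_model() -> ConditionModel:
    """Default antagonist (α-bungarotoxin, 0.2 µM) condition model."""
    return ConditionModel(
        label="BGT",
        populations=(
            PopulationParams(
                1.0, 7.385, 1.1555, math.sqrt(2.5735), math.sqrt(3.103)
            ),
        ),
        n_trajectories=176,
        ligand="alpha-bungarotoxin 0.2 uM",
    )


def default_condition_models() -> Dict[str, ConditionModel]:
    return {"CCh": cch_model(), "BGT": bgt_model()}


def _draw_lifetime_frames(rng: np.random.Generator, model: ConditionModel) -> int:
    """Geometric lifetime with mean mean_lifetime/frame_interval frames,
    clipped to [2, max_frames]."""
    mean_frames = model.mean_lifetime / model.frame_interval
    p = 1.0 / mean_frames
    return int(np.clip(rng.geometric(p), 2, model.max_frames))


def simulate_angular_trajectories(
    model: ConditionModel, seed: int
) -> List[AngularTrajectory]:
    """Draw an ensemble of angular trajectories from a condition model.

    Per trajectory: a population is drawn by weight, a lifetime from the
    clipped geometric law, then each axis performs Brownian rotation with
    per-step variance 2Dτ observed through additive Gaussian noise of SD
    σ, and the observed series is re-zeroed to its first sample.  The
    expected ensemble MSD per axis is 2σ² + 2D·Δt (single population).
    """
    root = np.random.SeedSequence(seed)
    children = root.spawn(model.n_trajectories)
    weights = np.array([p.weight for p in model.populations])
    tau = model.frame_interval
    out: List[AngularTrajectory] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        pop = model.populations[rng.choice(len(weights), p=weights)]
        n = _draw_lifetime_frames(rng, model)
        series = {}
        for axis, D, sigma in (
            ("theta", pop.D_theta, pop.sigma_theta),
            ("chi", pop.D_chi, pop.sigma_chi),
        ):
            steps = rng.normal(0.0, math.sqrt(2.0 * D * tau), size=n - 1)
            latent = np.concatenate([[0.0], np.cumsum(steps)])
            observed = latent + rng.normal(0.0, sigma, size=n)
            series[axis] = observed - observed[0]
        out.append(
            AngularTrajectory(
                trajectory_id=i,
                t=np.arange(n) * tau,
                theta=series["theta"],
                chi=series["chi"],
                condition_label=model.label,
            )
        )
    return out


@dataclass(frozen=True)
class RenderConfig:
    """Forward-model parameters for rendering detector movies."""

    geometry: BeamlineGeometry = field(default_factory=BeamlineGeometry)
    psf_sigma: float = 1.2  # px
    photons_per_spot: float = 5000.0  # mean counts per visible spot
    background: float = 10.0  # mean counts per pixel
    seed: int = 0
    shot_noise: bool = True  # Poisson-sample photons and background

    def __post_init__(self) -> None:
        if not self.psf_sigma > 0:
            raise ValueError("psf_sigma must be positive")
        if not self.photons_per_spot > 0:
            raise ValueError("photons_per_spot must be positive")
        if self.background < 0:
            raise ValueError("background must be non-negative")


def _spot_positions(
    tr: AngularTrajectory,
    plane: CrystalPlane,
    azimuth0: float,
    geometry: BeamlineGeometry,
) -> pd.DataFrame:
    """True detector centre and visibility of one crystal per frame.

    The crystal starts Bragg-matched to the peak energy; a tilt of θ mrad
    moves its Bragg angle by θ/1000 rad (so the scattering angle by
    2θ/1000), and its matched wavelength λ(t) = 2d·sin(θ_B(t)).  The spot
    is visible while λ(t) stays inside the beam's energy band and the
    centre stays on the detector.
    """
    band = ring_band(plane, geometry)
    theta_b0 = bragg_angle(plane, geometry.peak_energy)
    e_lo, e_hi = geometry.band_edges_kev
    lam_min, lam_max = wavelength(e_hi), wavelength(e_lo)
    rows, cols = geometry.detector_shape
    cy, cx = geometry.beam_center
    rec = []
    for j in range(len(tr.t)):
        theta_b = theta_b0 + tr.theta[j] / 1000.0
        lam = 2.0 * plane.d_spacing * math.sin(theta_b)
        in_band = lam_min <= lam <= lam_max
        r_px = geometry.camera_length * math.tan(2.0 * theta_b) / geometry.pixel_pitch
        az = azimuth0 + tr.chi[j] / 1000.0
        x = cx + r_px * math.cos(az)
        y = cy + r_px * math.sin(az)
        on_det = 0 <= x < cols and 0 <= y < rows
        rec.append(
            dict(trajectory_id=tr.trajectory_id, frame=j,
                 t_ms=tr.t[j], x_px=x, y_px=y, ring=plane.name,
                 visible=bool(in_band and on_det))
        )
    return pd.DataFrame.from_records(rec)


def render_movie(
    trajectories: Sequence[AngularTrajectory],
    render: RenderConfig,
    rings: Optional[Sequence[CrystalPlane]] = None,
    azimuths: Optional[Sequence[float]] = None,
    n_frames: Optional[int] = None,
    condition_label: str = "",
) -> Tuple[DetectorMovie, pd.DataFrame]:
    """Render angular trajectories into a detector movie.

    Each crystal is assigned a ring (alternating Au(111)/Au(200) unless
    ``rings`` is given) and an initial azimuth (uniform unless
    ``azimuths`` is given); per frame its spot is a 2-D Gaussian of width
    ``psf_sigma`` carrying ``photons_per_spot`` counts over a flat
    background, Poisson-sampled when ``shot_noise``.  A spot is omitted
    from frames where its tilt-implied wavelength leaves the energy band
    or its centre leaves the detector — the physical track-termination
    mechanism of DXT.

    Returns
    -------
    (movie, truth)
        The movie and a ground-truth table of true centres per frame with
        a ``visible`` flag.
    """
    if not trajectories:
        raise ValueError("no trajectories to render")
    geometry = render.geometry
    rng = np.random.default_rng(np.random.SeedSequence(render.seed))
    planes = list(rings) if rings is not None else [
        (AU111, AU200)[i % 2] for i in range(len(trajectories))
    ]
    if azimuths is None:
        azimuths = rng.uniform(-math.pi, math.pi, size=len(trajectories))
    if len(planes) != len(trajectories) or len(azimuths) != len(trajectories):
        raise ValueError("rings/azimuths must match the number of trajectories")

    truth = pd.concat(
        [_spot_positions(tr, pl, az, geometry)
         for tr, pl, az in zip(trajectories, planes, azimuths)],
        ignore_index=True,
    )
    T = n_frames if n_frames is not None else int(truth["frame"].max()) + 1
    T = max(T, 2)
    rows, cols = geometry.detector_shape
    expected = np.full((T, rows, cols), float(render.background))

    half = max(1, int(math.ceil(4 * render.psf_sigma)))
    norm = 2.0 * math.pi * render.psf_sigma**2
    for rec in truth.itertuples(index=False):
        if not rec.visible or rec.frame >= T:
            continue
        x0, y0 = rec.x_px, rec.y_px
        xi0, yi0 = int(round(x0)), int(round(y0))
        xs = np.arange(max(0, xi0 - half), min(cols, xi0 + half + 1))
        ys = np.arange(max(0, yi0 - half), min(rows, yi0 + half + 1))
        if xs.size == 0 or ys.size == 0:
            continue
        gx = np.exp(-((xs - x0) ** 2) / (2 * render.psf_sigma**2))
        gy = np.exp(-((ys - y0) ** 2) / (2 * render.psf_sigma**2))
        iy, ix = np.ix_(ys, xs)
        expected[rec.frame][iy, ix] += render.photons_per_spot / norm * np.outer(gy, gx)
    if render.shot_noise:
        frames = rng.poisson(expected).astype(np.uint16)
    else:
        frames = np.clip(np.round(expected), 0, 65535).astype(np.uint16)
    movie = DetectorMovie(
        frames=frames, frame_interval=geometry.frame_interval,
        geometry=geometry, condition_label=condition_label,
    )
    return movie, truth


def make_dataset(
    conditions: Sequence[ConditionModel],
    mode: str,
    seed: int,
    outdir: Path,
    render: Optional[RenderConfig] = None,
) -> dict:
    """Generate and write a per-condition dataset; returns the manifest.

    ``mode="angular"`` writes one trajectory CSV per condition;
    ``mode="movie"`` additionally renders multi-page TIFF movies with
    ground-truth CSVs.  Deterministic for a fixed seed: per-condition
    seeds are spawned from the root seed and recorded in the manifest.
    """
    from . import io as dxt_io  # local import to avoid cycle

    if not conditions:
        raise ValueError("condition list is empty")
    labels = [m.label for m in conditions]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate condition labels: {labels}")
    if mode not in ("angular", "movie"):
        raise ValueError(f"mode must be 'angular' or 'movie', got {mode!r}")

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(seed)
    cond_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(len(conditions))]

    manifest = {
        "seed": seed,
        "mode": mode,
        "conditions": {},
    }
    for model, cond_seed in zip(conditions, cond_seeds):
        trajs = simulate_angular_trajectories(model, cond_seed)
        csv_path = outdir / f"{model.label}_angular.csv"
        dxt_io.write_angular_csv(csv_path, trajs, condition_label=model.label)
        entry = {
            "seed": cond_seed,
            "n_trajectories": len(trajs),
            "angular_csv": csv_path.name,
            "model": _model_dict(model),
        }
        if mode == "movie":
            rc = render or RenderConfig()
            rc = RenderConfig(
                geometry=rc.geometry, psf_sigma=rc.psf_sigma,
                photons_per_spot=rc.photons_per_spot,
                background=rc.background, seed=cond_seed,
                shot_noise=rc.shot_noise,
            )
            movie, truth = render_movie(trajs, rc, condition_label=model.label)
            tif_path = outdir / f"{model.label}_movie.tif"
            truth_path = outdir / f"{model.label}_truth.csv"
            dxt_io.write_movie(tif_path, movie)
            truth.to_csv(truth_path, index=False)
            entry["movie_tiff"] = tif_path.name
            entry["truth_csv"] = truth_path.name
        manifest["conditions"][model.label] = entry

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _model_dict(model: ConditionModel) -> dict:
    d = asdict(model)
    d["populations"] = [asdict(p) for p in model.populations]
    return d
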