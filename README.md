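# dxtrack

Analysis tools for **diffracted X-ray tracking (DXT)** — a single-molecule
technique that reads a protein's orientation changes off the motion of
Bragg diffraction spots produced by a gold nanocrystal label under a
broadband X-ray beam.  The package targets the ligand-gated motion of the
nicotinic acetylcholine receptor (nAChR) on living myotubes: an agonist
(carbamylcholine, CCh) leaves the receptor free to twist, while the
antagonist α-bungarotoxin (BGT) locks it, suppressing twist (χ) rotations
above ~10 mrad while leaving tilt (θ) motion essentially unchanged.

## What it does

* **Geometry** (`dxtrack.geometry`) — Bragg-condition mathematics for the
  Au(111)/Au(200) rings: `λ = 2d·sinθ_B`, flat-detector ring radii
  `r = L·tan 2θ_B`, energy-band acceptance windows, detector↔polar
  transforms, and the tilt/twist decomposition
  `Δθ = Δ(2θ_spot)/2`, `Δχ = Δ(azimuth)`.
* **Tracking** (`dxtrack.tracking`) — Crocker–Grier-style spot detection
  (band-pass, robust threshold, sub-pixel centroids) and optimal
  frame-to-frame linking (Hungarian assignment with a birth/death
  penalty, no gap closing).
* **Kinetics** (`dxtrack.kinetics`, `dxtrack.models`) — ensemble
  mean-square displacement per axis over pooled trajectory pairs, with
  the linear model

      MSD(Δt) = 2σ² + 2D·Δt

  fitted by pair-count-weighted least squares (slope = 2D, the rotational
  diffusion coefficient; intercept = 2σ², the static noise variance);
  displacement distributions, tail fractions above a threshold, 2-D
  (|Δθ|, |Δχ|) probability-density maps and between-condition difference
  maps.
* **Synthetic data** (`dxtrack.synthetic`) — a calibrated generator
  (Brownian rotation + Gaussian static noise, geometric track lifetimes)
  whose default CCh/BGT condition models reproduce the published ensemble
  MSD slopes and intercepts, plus a physical movie renderer
  (ring geometry, band exits, Poisson photons) for end-to-end tests.
* **Pipeline & CLI** (`dxtrack.pipeline`, `dxt`) — config-driven
  simulate → track → analyze → compare runs with deterministic,
  byte-reproducible reports.

## Worked example

```python
from dxtrack import RotationalMSDModel, simulate_angular_trajectories, bgt_model

trajs = simulate_angular_trajectories(bgt_model(), seed=0)  # 176 trajectories
results = RotationalMSDModel(trajs).fit(lag_range=(0.1, 0.7))
print(results.summary())
```

```
Ensemble rotational MSD fit
================================================================
Condition:        BGT
Trajectories:     176
Mean track span:  0.768 ms
Fit lag range:    0.1-0.7 ms (7 lags, pair-count weighted)
----------------------------------------------------------------
axis       slope     (SE)   intercept     (SE)        D  sigma^2
       mrad^2/ms               mrad^2         mrad^2/ms   mrad^2
----------------------------------------------------------------
theta     11.557    0.471       5.284    0.187    5.779    2.642
chi        1.015    0.535       6.734    0.212    0.507    3.367
================================================================
```

The χ slope (here ≈ 1.0 mrad²/ms against a generative 2.311 mrad²/ms for
the antagonist condition — single-seed fits at n = 176 scatter by a few
SE) estimates twice the twist diffusion coefficient; the intercept is
twice the static angular-noise variance.  Note the printed SEs are the
curve-level weighted-fit values (the convention DXT studies quote);
`fit(cov_type="cluster")` gives trajectory-clustered SEs that honestly
reflect seed-to-seed scatter and are used for all between-condition
significance calls.

Comparing conditions from the shell:

```bash
dxt compare --a CCh --b BGT
# theta: slope 23.276 vs 13.152 mrad^2/ms, ratio 1.77, suppressed=False
# chi:   slope 10.473 vs 3.145 mrad^2/ms, ratio 3.33, suppressed=False
# net difference mass (chi 10-50 mrad): +0.0340
```

(Suppression is a 3-SE significance call on the clustered fits combined
with a slope-ratio threshold of 4; at n ≈ 160–180 short tracks a single
run hovers around that boundary — across seeds the χ call fires on ~4 of
5 runs while θ stays unsuppressed.)

## Data formats

Multi-page 16-bit TIFF movies; CSV trajectory tables
(`trajectory_id, frame, t_ms, x_px, y_px, intensity, ring`); angular
tables (`trajectory_id, t_ms, theta_mrad, chi_mrad, ring, condition`);
JSON reports with config-hash provenance.  See `docs/methods.md` for the
model, assumptions, parameter defaults and limitations.
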