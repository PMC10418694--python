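# Methods

## The measurement being modelled

In diffracted X-ray tracking, a ~20–60 nm gold nanocrystal is conjugated
(via an antibody Fab' fragment) to the extracellular domain of a membrane
receptor and illuminated with a quasi-white X-ray beam (peak 15.8 keV,
fractional bandwidth ΔE/E = 0.08, ~10¹³ photons/s, 50 mm camera length,
100 µs frames, ≤10 ms records).  The crystal's Au(111) or Au(200) planes
Bragg-diffract whenever their orientation matches some wavelength inside
the band, so a *tilting* crystal moves its diffraction spot radially and a
*twisting* crystal (rotation about the beam axis) moves it azimuthally.
Tracking spots frame-to-frame therefore yields per-molecule angular
trajectories θ(t) (tilt) and χ(t) (twist) in milliradians.

Key geometric relations (module `geometry`):

* wavelength λ [Å] = 12.3984 / E [keV];
* Bragg angle θ_B = arcsin(λ / 2d), with d(111) = a/√3 = 2.3546 Å and
  d(200) = a/2 = 2.0391 Å for the gold lattice constant a = 4.0782 Å;
* flat-detector ring radius r = L·tan 2θ_B (L = camera length), giving
  defaults r(111) ≈ 17.40 mm and r(200) ≈ 20.39 mm;
* a rectangular energy band [E(1−w/2), E(1+w/2)] maps to radial
  acceptance bands ≈ [16.67, 18.19] mm (111) and [19.52, 21.35] mm (200):
  a spot is observable iff its tilt-implied wavelength is in band;
* crystal tilt is half the scattering-angle change, Δθ = Δ(2θ_spot)/2;
  twist maps 1:1 to azimuth, wrapped into (−π, π].  θ–χ cross-talk is
  neglected — valid in the ≤100 mrad regime these measurements occupy.

The published experiment states the band as "0.08"; we read this as the
dimensionless fractional width ΔE/E (a literal 0.08 nm would be larger
than the 15.8 keV wavelength of 0.0785 nm and is taken to be a units
slip).  The band profile is modelled as rectangular — the simplest shape
consistent with spots appearing "around" the nominal ring radii; real
undulator spectra taper, which would soften band-edge terminations.

Dose bookkeeping uses the linear rate implied by the published
cell-viability bounds: 1.13 kGy/ms, so 10 ms → 11.3 kGy (tolerated) and
100 ms → 113 kGy (lethal).  10 mrad — the twist amplitude whose
suppression distinguishes the antagonist — is 0.57°, i.e. the published
0.6° lower bound.

## Tracking

Detection is Crocker–Grier style: difference-of-Gaussians band-pass
(σ = 1 px vs the minimum separation), candidate pixels are local maxima
above median + k·(1.4826·MAD) of the filtered frame (default k = 5),
sub-pixel centres are intensity-weighted centroids over a window of
radius `min_separation` (default 5 px), and overlapping candidates
within that separation collapse to the brighter one.

Linking solves, per consecutive frame pair, the assignment minimising
Σd² + max_displacement²·(number of unmatched spots) over pairs gated at
d ≤ max_displacement (default 10 px), via the Hungarian algorithm on a
dummy-augmented cost matrix.  The per-spot birth/death penalty makes the
bare "minimum total squared displacement" objective well-posed (the empty
matching would otherwise be optimal) and reproduces the behaviour of
standard particle-tracking software.  There is **no gap closing**
(memory = 0): with 0.7 ms mean lifetimes over 0.1 ms frames, bridging
dropouts would manufacture spurious long trajectories.  Spots are sorted
into canonical (row, col) order before assignment, so results are
deterministic and invariant to input order.  At the linking stage every
detected spot belongs to exactly one track, singletons included;
`filter_trajectories` then drops tracks shorter than 2 frames and tracks
whose majority ring label (≥80% of spots inside one band) is undefined,
and logs kept/discarded counts and mean track duration.

## The kinetic model and its estimator

Each axis is modelled as free rotational Brownian motion observed through
static angular noise:

    x_obs(t) = x(t) + ε(t),   Var[x(t+Δ)−x(t)] = 2D·Δ,   ε ~ N(0, σ²) i.i.d.

giving the ensemble MSD the linear form **MSD(Δt) = 2σ² + 2D·Δt**.

The estimator pools every ordered in-trajectory sample pair (i, i+k)
across all trajectories (time-and-ensemble average), k = 1..7, i.e. lags
0.1–0.7 ms — the mean trackable span.  The line is fitted by weighted
least squares with weights proportional to the per-lag pair counts.
Au(111) and Au(200) trajectories are pooled after per-ring angular
conversion.

**Standard errors — two flavours, deliberately.**  `fit_msd_linear`
reports the curve-level weighted-LSQ SEs (covariance scaled by residual
variance), which is the convention single-molecule MSD studies print.
These SEs assume the seven MSD points are independent; they are not —
overlapping pairs from one trajectory share the same diffusion path — and
simulation shows they understate the seed-to-seed scatter of the fitted
slope several-fold at n ≈ 160 short tracks.  `fit_msd_cluster` therefore
refits the same line at the level of individual squared pair
displacements (numerically identical point estimates, since the regressor
is constant within a lag) and takes the covariance clustered by
trajectory; these SEs agree with a trajectory bootstrap and with the
observed across-seed scatter.  All inference in the package — recovery
checks and the between-condition suppression call — uses the clustered
SEs; the suppression call itself is the standard two-sample criterion
|Δslope| > 3·√(SE_a² + SE_b²) combined with a slope-ratio threshold
(default 4), rather than requiring disjoint ±3 SE intervals (which is an
unconventionally strict ~4.2σ test).

Displacement distributions and the 2-D (|Δθ|, |Δχ|) probability maps use
absolute displacements at a fixed lag (default Δt = 0.7 ms) on 60
log-spaced bins spanning 0.01–1000 mrad; 1-D distributions carry explicit
underflow/overflow masses so they total exactly 1, 2-D maps normalise
over in-range pairs.  Difference maps are cell-wise a − b and sum to 0;
the net mass in the χ ∈ [10, 50] mrad cells is reported as the
gating-band signature.  The tail fraction is the proportion of pooled
|displacements| strictly above threshold (default 10 mrad).

Whether the published distributions pooled all pairs or only trajectories
surviving ≥ 0.7 ms is not stated; this implementation pools all pairs at
the requested lag.

## The synthetic generator

The original raw trajectories are not publicly deposited, so the
generator is the package's stand-in for the study data.  Defaults encode
the published study conditions:

| parameter | CCh | BGT | origin |
|---|---|---|---|
| n trajectories | 157 | 176 | published counts |
| frame interval | 0.1 ms | 0.1 ms | 100 µs resolution |
| mean lifetime | 0.7 ms | 0.7 ms | published mean span |
| record cap | 10 ms | 10 ms | acquisition length |
| D_θ (mrad²/ms) | 10.35 | 7.385 | slope/2 |
| D_χ (mrad²/ms) | 9.225 | 1.1555 | slope/2 |
| σ²_θ (mrad²) | 3.5715 | 2.5735 | intercept/2 |
| σ²_χ (mrad²) | 7.398 | 3.103 | intercept/2 |

Lifetimes are geometric (memoryless per-frame termination) with mean 7
frames, clipped to [2, 100]; the clip raises the mean to ≈7.14 frames
(0.714 ms), within the 15% envelope of the target.  A trajectory of L
frames is counted as spanning L·0.1 ms.  Axes evolve independently;
observations are re-zeroed to the first sample (which leaves pair
displacements unchanged).  The full MSD intercept is attributed to
measurement noise — the data cannot separate static noise from unresolved
fast wobble, so σ² here is an upper bound on localisation noise.  An
optional two-population CCh variant (30% "gating" molecules carrying the
twist excess over an antagonist-like baseline, weights preserving the
ensemble slope) exists for heavy-tail experiments; all defaults are
single-population, which already reproduces the published tail contrast
(χ tail beyond 10 mrad at 0.7 ms: ≈5.7% for CCh vs ≈0.04% for BGT by the
Gaussian tail formula).

What the generator does **not** emulate: open/closed state-switching
kinetics (the MSD data constrain none), detector/intensifier photophysics
beyond Poisson counting, beam drift, and radiation damage.  Passing
recovery tests therefore demonstrate estimator correctness under the
stated diffusion-plus-noise model, not robustness to those real-world
effects.

The movie renderer is the forward model of the geometry module: each
crystal starts Bragg-matched at the peak energy on an alternating ring
with a random azimuth, its spot is a 2-D Gaussian (σ = 1.2 px,
5000 photons) over flat background with optional Poisson sampling, and
the spot vanishes in frames where the tilt-implied wavelength leaves the
energy band or the centre leaves the 512×512 detector (at 0.08 mm/px the
outer Au(200) band edge is on-detector only off-axis, so uniform-azimuth
renders lose some Au(200) frames — a physical truncation, kept).

Seeding is hierarchical: one integer seed spawns per-trajectory
`SeedSequence` children (condition → trajectory → frame), so datasets are
bit-reproducible and any subset is independently regenerable.

## Numerical and design choices

* Angles in radians internally, mrad in all reported quantities; times in
  ms; energies keV; detector lengths mm (pixels only at I/O boundaries).
* Azimuth wrap into (−π, π] uses IEEE remainder; trajectories straddling
  the seam give MSDs identical to rotated copies to <10⁻⁹ relative.
* Equal-cost assignments in linking are broken by canonical spot order;
  ties have measure zero for sub-pixel centroids.
* A saturated 2-lag fit has zero residual degrees of freedom; its SEs are
  reported as 0.
* Degenerate inputs raise: empty ensembles, lags with no pairs,
  mismatched map binning, non-finite frames, off-detector beam centres,
  λ > 2d (no diffraction), points at the beam centre (undefined azimuth).
* CSV floats are written at 17 significant digits and parsed with
  pandas' round-trip parser, so write→read is the identity; reports carry
  a config hash, seed and version but no timestamps, making reruns
  byte-identical.
* Problem sizes in tests and the acceptance script follow the study
  conditions themselves (≤180 trajectories per condition, 5 replicate
  seeds, one 512×512 rendered movie per end-to-end check), which keeps
  the full suite interactive on a single CPU.

## Known limitations

* The tilt/twist decomposition ignores θ–χ coupling and detector
  distortion; fine for ≤100 mrad excursions, wrong near grazing exits.
* The rectangular band and single-energy Bragg matching idealise a real
  undulator spectrum and crystal mosaicity.
* The weighted-LSQ SEs quoted alongside slopes mirror the field's
  convention but are optimistic as sampling errors (see above); use the
  clustered SEs for any significance statement.
* With ~160 trajectories of ~7 frames, the fitted slope of a slow axis
  (BGT χ, 2.311 mrad²/ms) has a clustered SE near 1 mrad²/ms — single
  runs scatter accordingly, and even 5-seed means retain ~15% relative
  scatter.  This is intrinsic to the study size, not the estimator.
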