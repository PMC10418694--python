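"""Bragg-condition mathematics and detector <-> angle coordinate transforms.

In diffracted X-ray tracking (DXT) a gold nanocrystal attached to a protein
diffracts a broadband X-ray beam.  The diffraction spot's radial position on
the detector encodes the crystal's tilt (θ, via the scattering angle 2θ) and
its azimuthal position encodes the crystal's twist about the beam axis (χ).
Everything that converts a detector coordinate into an angle — and therefore
defines what a spot's motion *means* — lives in this module.

Conventions
-----------
* Angles are stored in radians internally and reported in milliradians.
* Energies are in keV, wavelengths in Å, lengths on the detector in mm,
  time in ms.
* Crystal tilt maps to radial spot motion as Δθ_crystal = Δ(2θ_spot)/2;
  twist maps one-to-one onto the spot azimuth.  Cross-talk between the two
  is neglected, which is accurate in the small-angle regime (displacements
  of at most ~100 mrad) that DXT operates in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

__all__ = [
    "HC_KEV_ANGSTROM",
    "GOLD_LATTICE_ANGSTROM",
    "AU111",
    "AU200",
    "BeamlineGeometry",
    "CrystalPlane",
    "RingBand",
    "NoDiffractionError",
    "bragg_angle",
    "ring_radius",
    "ring_band",
    "default_bands",
    "detector_to_polar",
    "polar_to_detector",
    "classify_ring",
    "angular_displacement",
    "wrap_angle",
    "mrad_to_degrees",
    "degrees_to_mrad",
    "dose",
]

#: h·c in keV·Å, so that wavelength λ [Å] = HC_KEV_ANGSTROM / E [keV].
HC_KEV_ANGSTROM = 12.3984

#: Lattice constant of fcc gold, Å.
GOLD_LATTICE_ANGSTROM = 4.0782


class NoDiffractionError(ValueError):
    """Raised when the Bragg condition has no solution (λ > 2d)."""


@dataclass(frozen=True)
class CrystalPlane:
    """A lattice-plane family of the gold label, identified by its d-spacing.

    Parameters
    ----------
    name : str
        Label, e.g. ``"Au111"``.
    d_spacing : float
        Lattice plane spacing in Å.
    """

    name: str
    d_spacing: float

    def __post_init__(self) -> None:
        if not self.d_spacing > 0:
            raise ValueError(f"d_spacing must be positive, got {self.d_spacing}")


#: Au(111): d = a/√3 for the fcc lattice constant a = 4.0782 Å.
AU111 = CrystalPlane("Au111", GOLD_LATTICE_ANGSTROM / math.sqrt(3.0))
#: Au(200): d = a/2.
AU200 = CrystalPlane("Au200", GOLD_LATTICE_ANGSTROM / 2.0)


@dataclass(frozen=True)
class BeamlineGeometry:
    """Acquisition geometry of a DXT measurement.

    Defaults reproduce the experimental configuration the analysis targets:
    15.8 keV peak energy with fractional bandwidth ΔE/E = 0.08, a 50 mm
    camera length and 100 µs frames.

    Parameters
    ----------
    peak_energy : float
        Photon energy at the centre of the band, keV.
    fractional_bandwidth : float
        Dimensionless full width ΔE/E of the (rectangular) energy band.
    camera_length : float
        Sample-to-detector distance, mm.
    pixel_pitch : float
        Detector pixel size, mm per pixel.
    beam_center : (float, float)
        Direct-beam position on the detector as (row, col) in pixels.
    detector_shape : (int, int)
        Detector size as (rows, cols) in pixels.
    frame_interval : float
        Time per frame, ms.
    beam_diameter : float
        Beam size at the sample, mm (metadata only).
    """

    peak_energy: float = 15.8
    fractional_bandwidth: float = 0.08
    camera_length: float = 50.0
    pixel_pitch: float = 0.08
    beam_center: Tuple[float, float] = (255.5, 255.5)
    detector_shape: Tuple[int, int] = (512, 512)
    frame_interval: float = 0.1
    beam_diameter: float = 0.05

    def __post_init__(self) -> None:
        if not self.peak_energy > 0:
            raise ValueError("peak_energy must be positive")
        if not 0 < self.fractional_bandwidth < 1:
            raise ValueError("fractional_bandwidth must be in (0, 1)")
        if not self.camera_length > 0:
            raise ValueError("camera_length must be positive")
        if not self.pixel_pitch > 0:
            raise ValueError("pixel_pitch must be positive")
        if not self.frame_interval > 0:
            raise ValueError("frame_interval must be positive")
        rows, cols = self.detector_shape
        cy, cx = self.beam_center
        if not (0 <= cy < rows and 0 <= cx < cols):
            raise ValueError(
                f"beam_center {self.beam_center} outside detector {self.detector_shape}"
            )

    @property
    def band_edges_kev(self) -> Tuple[float, float]:
        """(low, high) edge energies of the rectangular band, keV."""
        w = self.fractional_bandwidth
        return (self.peak_energy * (1 - w / 2), self.peak_energy * (1 + w / 2))


@dataclass(frozen=True)
class RingBand:
    """Radial window on the detector inside which a plane can diffract.

    Because the beam is broadband, a crystal keeps satisfying the Bragg
    condition over a range of tilts; the diffraction ring is a radial band
    ``[r_min, r_max]`` rather than a sharp circle.
    """

    plane: CrystalPlane
    r_min: float
    r_max: float

    def __post_init__(self) -> None:
        if not 0 < self.r_min < self.r_max:
            raise ValueError(
                f"require 0 < r_min < r_max, got [{self.r_min}, {self.r_max}]"
            )

    def contains(self, r_mm: float) -> bool:
        return self.r_min <= r_mm <= self.r_max


def wavelength(energy_kev: float) -> float:
    """Photon wavelength in Å for an energy in keV."""
    if not energy_kev > 0:
        raise ValueError("energy must be positive")
    return HC_KEV_ANGSTROM / energy_kev


def bragg_angle(plane: CrystalPlane, energy_kev: float) -> float:
    """First-order Bragg angle θ_B (radians) of `plane` at `energy_kev`.

    Solves λ = 2 d sin θ_B.  Strictly decreasing in energy.

    Raises
    ------
    NoDiffractionError
        If λ > 2d, i.e. the Bragg condition has no solution.
    """
    lam = wavelength(energy_kev)
    s = lam / (2.0 * plane.d_spacing)
    if s > 1.0:
        raise NoDiffractionError(
            f"no diffraction from {plane.name} at {energy_kev} keV: "
            f"λ = {lam:.4f} Å exceeds 2d = {2 * plane.d_spacing:.4f} Å"
        )
    return math.asin(s)


def ring_radius(theta_b: float, geometry: BeamlineGeometry) -> float:
    """Radial distance (mm) at which the Bragg cone of half-angle 2θ_B hits
    a flat detector at the geometry's camera length.

    Raises
    ------
    ValueError
        If 2θ_B ≥ 90° (back-scattering, outside the flat-detector model).
    """
    two_theta = 2.0 * theta_b
    if not 0 <= two_theta < math.pi / 2:
        raise ValueError(
            f"scattering angle 2θ = {math.degrees(two_theta):.2f}° outside [0°, 90°)"
        )
    return geometry.camera_length * math.tan(two_theta)


def ring_band(plane: CrystalPlane, geometry: BeamlineGeometry) -> RingBand:
    """Radial band spanned by `plane` across the energy band.

    The high-energy band edge has the shortest wavelength, hence the
    smallest Bragg angle and the inner radius; the low edge gives the outer
    radius.
    """
    e_lo, e_hi = geometry.band_edges_kev
    r_min = ring_radius(bragg_angle(plane, e_hi), geometry)
    r_max = ring_radius(bragg_angle(plane, e_lo), geometry)
    return RingBand(plane, r_min, r_max)


def default_bands(geometry: Optional[BeamlineGeometry] = None) -> Tuple[RingBand, RingBand]:
    """The Au(111) and Au(200) bands for `geometry` (defaults if None)."""
    geometry = geometry or BeamlineGeometry()
    return (ring_band(AU111, geometry), ring_band(AU200, geometry))


def detector_to_polar(
    x: float, y: float, geometry: BeamlineGeometry
) -> Tuple[float, float]:
    """Convert a detector position to scattering-polar coordinates.

    Parameters
    ----------
    x, y : float
        Detector position in pixels; ``x`` is the column coordinate and
        ``y`` the row coordinate.
    geometry : BeamlineGeometry

    Returns
    -------
    (two_theta, chi) : tuple of float
        ``two_theta`` — full scattering angle arctan(r/L) in radians;
        ``chi`` — azimuth in (−π, π], counter-clockwise from the +column
        axis (+row axis at +π/2).

    Raises
    ------
    ValueError
        If the point coincides with the beam centre (azimuth undefined).
    """
    cy, cx = geometry.beam_center
    dx = (x - cx) * geometry.pixel_pitch
    dy = (y - cy) * geometry.pixel_pitch
    r = math.hypot(dx, dy)
    if r == 0.0:
        raise ValueError("azimuth undefined exactly at the beam centre")
    two_theta = math.atan(r / geometry.camera_length)
    chi = math.atan2(dy, dx)
    if chi <= -math.pi:  # atan2 returns (-π, π]; normalise the -π edge
        chi += 2 * math.pi
    return two_theta, chi


def polar_to_detector(
    two_theta: float, chi: float, geometry: BeamlineGeometry
) -> Tuple[float, float]:
    """Inverse of :func:`detector_to_polar`; returns (x, y) in pixels."""
    if not 0 <= two_theta < math.pi / 2:
        raise ValueError("two_theta outside [0, 90°)")
    r_px = geometry.camera_length * math.tan(two_theta) / geometry.pixel_pitch
    cy, cx = geometry.beam_center
    return (cx + r_px * math.cos(chi), cy + r_px * math.sin(chi))


def _validate_bands(bands: Sequence[RingBand]) -> None:
    ordered = sorted(bands, key=lambda b: b.r_min)
    for a, b in zip(ordered, ordered[1:]):
        if b.r_min <= a.r_max:
            raise ValueError(
                f"ring bands overlap: {a.plane.name} [{a.r_min:.3f}, {a.r_max:.3f}] "
                f"and {b.plane.name} [{b.r_min:.3f}, {b.r_max:.3f}] mm"
            )


def classify_ring(
    spot_polar: Tuple[float, float],
    bands: Sequence[RingBand],
    geometry: Optional[BeamlineGeometry] = None,
) -> Optional[str]:
    """Assign a spot to the unique ring band containing its radius.

    Parameters
    ----------
    spot_polar : (two_theta, chi)
        Polar coordinates as returned by :func:`detector_to_polar`.
    bands : sequence of RingBand
        Candidate bands; must be pairwise non-overlapping.
    geometry : BeamlineGeometry, optional
        Supplies the camera length for the radius; defaults used if None.

    Returns
    -------
    str or None
        The plane name, or None if the radius falls in no band.
    """
    _validate_bands(bands)
    geometry = geometry or BeamlineGeometry()
    r = geometry.camera_length * math.tan(spot_polar[0])
    for band in bands:
        if band.contains(r):
            return band.plane.name
    return None


def wrap_angle(angle: float) -> float:
    """Wrap an angle in radians into (−π, π]."""
    wrapped = math.remainder(angle, 2 * math.pi)  # (-π, π], with -π possible
    if wrapped <= -math.pi:
        wrapped += 2 * math.pi
    return wrapped


def angular_displacement(
    p1: Tuple[float, float],
    p2: Tuple[float, float],
    bands: Optional[Sequence[RingBand]] = None,
    geometry: Optional[BeamlineGeometry] = None,
) -> Tuple[float, float]:
    """Crystal rotation (Δθ, Δχ) in mrad between two spot positions.

    The tilt is half the change in scattering angle (the diffraction
    condition doubles crystal tilt into 2θ motion); the twist is the
    wrapped azimuth change, taken along the short way around the ring.

    Parameters
    ----------
    p1, p2 : (two_theta, chi)
        Polar spot coordinates in radians.
    bands : sequence of RingBand, optional
        If given, both points must classify to the same plane; points on
        two *different* planes raise (a radial move of that size is a ring
        jump, not a rotation).

    Returns
    -------
    (dtheta, dchi) : tuple of float, mrad
    """
    if bands is not None:
        ring1 = classify_ring(p1, bands, geometry)
        ring2 = classify_ring(p2, bands, geometry)
        if ring1 is not None and ring2 is not None and ring1 != ring2:
            raise ValueError(
                f"points lie on different rings ({ring1} vs {ring2}); "
                "angular displacement is undefined across rings"
            )
    dtheta = 1000.0 * (p2[0] - p1[0]) / 2.0
    dchi = 1000.0 * wrap_angle(p2[1] - p1[1])
    return dtheta, dchi


def mrad_to_degrees(angle_mrad: float) -> float:
    """Convert milliradians to degrees (10 mrad ≈ 0.57°)."""
    return angle_mrad * 180.0 / (1000.0 * math.pi)


def degrees_to_mrad(angle_deg: float) -> float:
    """Convert degrees to milliradians."""
    return angle_deg * 1000.0 * math.pi / 180.0


def dose(exposure_ms: float, dose_rate_kgy_per_ms: float = 1.13) -> float:
    """Absorbed dose (kGy) for an exposure time, at the beamline's dose rate.

    The default rate, 1.13 kGy/ms, is the rate at which 100 ms of
    irradiation deposits 113 kGy (the cell-death threshold measurement)
    and 10 ms deposits 11.3 kGy (tolerated by the myotubes).

    Raises
    ------
    ValueError
        For negative exposure or non-positive rate.
    """
    if exposure_ms < 0:
        raise ValueError("exposure must be non-negative")
    if not dose_rate_kgy_per_ms > 0:
        raise ValueError("dose rate must be positive")
    return exposure_ms * dose_rate_kgy_per_ms
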