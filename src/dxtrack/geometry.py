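"""Detector geometry for Laue spots: Bragg angles, detector mapping, ring
assignment and the energy-bandwidth acceptance used by the lifetime model.

A pink (polychromatic) beam of peak energy ``E`` and fractional bandwidth
``dE/E`` excites a reflection of spacing ``d`` over a finite range of crystal
tilts.  Differentiating Bragg's law at fixed ``d`` gives the scattering-angle
acceptance ``delta(2theta) ~ tan(theta_B) * dE/E``, which is the window a
spot must stay inside to remain visible — the physical origin of the
lifetime/speed coupling exploited by lifetime filtering.

Angles are radians throughout this module; the trajectory-analysis modules
work in mrad displacements where absolute offsets cancel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import GeometryError, NoDiffractionError

__all__ = [
    "DetectorGeometry",
    "Reflection",
    "DEFAULT_REFLECTIONS",
    "bragg_angle",
    "bragg_window",
    "angles_to_detector",
    "detector_to_angles",
    "assign_ring",
]

#: keV * Angstrom conversion constant (h*c).
HC_KEV_ANGSTROM = 12.3984


@dataclass(frozen=True)
class DetectorGeometry:
    """Flat-detector recording geometry of a DXT beamline."""

    sample_detector_distance: float  # mm
    beam_center: tuple[float, float] = (0.0, 0.0)  # mm
    peak_energy: float = 15.8  # keV
    bandwidth_fraction: float = 0.1  # dE/E

    def __post_init__(self) -> None:
        if self.sample_detector_distance <= 0:
            raise GeometryError("sample-detector distance must be > 0")
        if not 0 < self.bandwidth_fraction < 1:
            raise GeometryError("bandwidth_fraction must be in (0, 1)")


@dataclass(frozen=True)
class Reflection:
    """A powder reflection identified by label and d-spacing (Angstrom)."""

    label: str
    d_spacing: float

    def __post_init__(self) -> None:
        if self.d_spacing <= 0:
            raise GeometryError("d_spacing must be > 0")


#: Reflections used for spot assignment: gold nanocrystal Au(111) and the
#: three strong ZnO rings.  d-spacings are standard lattice values and can
#: be overridden per run.
DEFAULT_REFLECTIONS = (
    Reflection("Au(111)", 2.3549),
    Reflection("ZnO(100)", 2.8143),
    Reflection("ZnO(002)", 2.6033),
    Reflection("ZnO(101)", 2.4759),
)


def wavelength(energy_kev: float) -> float:
    """Photon wavelength in Angstrom for an energy in keV."""
    if energy_kev <= 0:
        raise GeometryError("energy must be > 0")
    return HC_KEV_ANGSTROM / energy_kev


def bragg_angle(reflection: Reflection, energy_kev: float) -> float:
    """Bragg angle theta_B (rad) of a reflection at a photon energy.

    Raises
    ------
    NoDiffractionError
        If the wavelength exceeds 2d and the Bragg condition cannot be met.
    """
    lam = wavelength(energy_kev)
    s = lam / (2.0 * reflection.d_spacing)
    if s > 1.0:
        raise NoDiffractionError(
            f"{reflection.label}: wavelength {lam:.4f} A > 2d = "
            f"{2 * reflection.d_spacing:.4f} A at {energy_kev} keV"
        )
    return math.asin(s)


def bragg_window(reflection: Reflection, geometry: DetectorGeometry) -> float:
    """Scattering-angle acceptance delta(2theta) (rad) from the bandwidth.

    First-order in dE/E: delta(2theta) = tan(theta_B) * dE/E.  Strictly
    positive and increasing in the bandwidth fraction.
    """
    theta_b = bragg_angle(reflection, geometry.peak_energy)
    return math.tan(theta_b) * geometry.bandwidth_fraction


def angles_to_detector(
    two_theta: float, chi: float, geometry: DetectorGeometry
) -> tuple[float, float]:
    """Map (2theta, chi) to a flat-detector position in mm.

    Tangent-plane mapping: radius r = L*tan(2theta), azimuth chi measured
    from the +x detector axis.

    Raises
    ------
    GeometryError
        If ``two_theta`` is negative or >= pi/2 (ray parallel to or behind
        the detector plane).
    """
    if not 0 <= two_theta < math.pi / 2:
        raise GeometryError(
            f"two_theta = {two_theta} rad outside [0, pi/2): off detector"
        )
    r = geometry.sample_detector_distance * math.tan(two_theta)
    x0, y0 = geometry.beam_center
    return x0 + r * math.cos(chi), y0 + r * math.sin(chi)


def detector_to_angles(
    x: float, y: float, geometry: DetectorGeometry
) -> tuple[float, float]:
    """Inverse of :func:`angles_to_detector`; chi returned in (-pi, pi].

    A point on the -x axis maps to chi = +pi (the branch cut closes on the
    positive side).  The beam center itself has no defined azimuth.
    """
    if not (math.isfinite(x) and math.isfinite(y)):
        raise GeometryError("detector position must be finite")
    dx = x - geometry.beam_center[0]
    dy = y - geometry.beam_center[1]
    r = math.hypot(dx, dy)
    if r == 0.0:
        raise GeometryError("chi undefined at the beam center")
    two_theta = math.atan2(r, geometry.sample_detector_distance)
    chi = math.atan2(dy, dx)
    if chi == -math.pi:
        chi = math.pi
    return two_theta, chi


def assign_ring(
    two_theta: float,
    reflections=DEFAULT_REFLECTIONS,
    geometry: DetectorGeometry | None = None,
) -> Reflection | None:
    """Assign a scattering angle to the nearest reflection within tolerance.

    The per-reflection tolerance is the bandwidth acceptance
    ``bragg_window``.  The nearest reflection (in |2theta - 2theta_B|) wins;
    exact ties are broken by list order.  Returns ``None`` when no
    reflection lies within its own tolerance.
    """
    if geometry is None:
        geometry = DetectorGeometry(sample_detector_distance=45.6)
    if not reflections:
        raise GeometryError("reflection list must be non-empty")
    best: Reflection | None = None
    best_dist = math.inf
    for refl in reflections:
        theta_b = bragg_angle(refl, geometry.peak_energy)
        dist = abs(two_theta - 2.0 * theta_b)
        if dist <= bragg_window(refl, geometry) and dist < best_dist:
            best = refl
            best_dist = dist
    return best
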