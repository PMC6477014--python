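"""Closed-form acoustics shared by the echo simulator and feature extractor.

Conventions used throughout the package: depths in mm, times in µs,
velocities in m/s, frequencies in MHz, gains/levels in dB.  Every function
converts internally and never leaks other units.

The attenuation coefficient is quoted per cm of *depth* (the usual clinical
round-trip convention), so ``tgc_gain`` — the time-gain-control curve that
restores amplitudes against soft-tissue absorption — is simply the
coefficient times the one-way path length implied by the time of flight.
"""
from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = [
    "MediumProperties",
    "BladderGeometry",
    "MEDIA",
    "FAT",
    "MUSCLE",
    "URINE",
    "SOFT_TISSUE",
    "PENETRATION_TABLE_CM",
    "time_of_flight",
    "depth_from_tof",
    "attenuation_coeff",
    "penetration_depth",
    "wall_thickness",
    "anterior_reflection_fraction",
    "tgc_gain",
]


@dataclass(frozen=True)
class MediumProperties:
    """Acoustic properties of a propagation medium.

    velocity is the longitudinal sound speed in m/s; attenuation_per_mhz is
    the absorption coefficient in dB/cm per MHz (linear in frequency).
    """

    name: str
    velocity: float
    attenuation_per_mhz: float

    def __post_init__(self) -> None:
        if self.velocity <= 0:
            raise ValueError(f"velocity must be positive, got {self.velocity}")
        if self.attenuation_per_mhz < 0:
            raise ValueError("attenuation_per_mhz must be non-negative")


@dataclass(frozen=True)
class BladderGeometry:
    """Axial geometry of the bladder along the beam.

    anterior_wall_depth: transducer-to-anterior-wall distance, mm (≈40 mm
    supine).  lumen_depth_extent: inner anterior-to-posterior distance, mm;
    zero exactly when the bladder is empty (it distends in depth first as it
    fills).  wall_thickness shrinks from ≈5 mm (empty) to ≈3 mm (full).
    """

    anterior_wall_depth: float
    fill_fraction: float
    wall_thickness: float
    lumen_depth_extent: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fill_fraction <= 1.0:
            raise ValueError("fill_fraction must lie in [0, 1]")
        if not 3.0 <= self.wall_thickness <= 5.0:
            raise ValueError("wall_thickness must lie in [3, 5] mm")
        if self.lumen_depth_extent < 0:
            raise ValueError("lumen_depth_extent must be non-negative")
        if self.fill_fraction == 0.0 and self.lumen_depth_extent != 0.0:
            raise ValueError("empty bladder must have zero lumen extent")

    @property
    def posterior_wall_depth(self) -> float:
        """Depth of the posterior-wall interface, mm."""
        return self.anterior_wall_depth + self.wall_thickness + self.lumen_depth_extent


def _load_media() -> dict[str, MediumProperties]:
    out: dict[str, MediumProperties] = {}
    with resources.files("prevoid.data").joinpath("media.csv").open("r") as fh:
        for row in csv.DictReader(fh):
            out[row["name"]] = MediumProperties(
                name=row["name"],
                velocity=float(row["velocity_m_per_s"]),
                attenuation_per_mhz=float(row["attenuation_db_per_cm_per_mhz"]),
            )
    return out


#: packaged medium table (fat / muscle / urine / soft_tissue)
MEDIA: dict[str, MediumProperties] = _load_media()
FAT = MEDIA["fat"]
MUSCLE = MEDIA["muscle"]
URINE = MEDIA["urine"]
SOFT_TISSUE = MEDIA["soft_tissue"]

#: penetration depth of ultrasound in the body vs frequency (cm); every cell
#: equals floor(40 / f_MHz)
PENETRATION_TABLE_CM: dict[float, int] = {1: 40, 2: 20, 3: 13, 5: 8, 10: 4, 20: 2}


def time_of_flight(depth_mm, velocity_m_s: float):
    """Round-trip pulse travel time T = 2D/c to an interface, in µs.

    Accepts scalar or array depths.
    """
    if velocity_m_s <= 0:
        raise ValueError(f"velocity must be positive, got {velocity_m_s}")
    depth = np.asarray(depth_mm, dtype=float)
    if np.any(depth < 0):
        raise ValueError("depth must be non-negative")
    tof = 2.0 * depth / (velocity_m_s * 1e-3)  # mm / (mm/µs)
    return float(tof) if np.isscalar(depth_mm) else tof


def depth_from_tof(tof_us, velocity_m_s: float):
    """Inverse of :func:`time_of_flight`: one-way depth in mm."""
    if velocity_m_s <= 0:
        raise ValueError(f"velocity must be positive, got {velocity_m_s}")
    tof = np.asarray(tof_us, dtype=float)
    depth = 0.5 * tof * velocity_m_s * 1e-3
    return float(depth) if np.isscalar(tof_us) else depth


def attenuation_coeff(freq_mhz: float, medium: MediumProperties = SOFT_TISSUE) -> float:
    """Absorption coefficient at ``freq_mhz``, dB/cm (linear frequency scaling)."""
    if freq_mhz <= 0:
        raise ValueError(f"frequency must be positive, got {freq_mhz}")
    return freq_mhz * medium.attenuation_per_mhz


def penetration_depth(freq_mhz: float) -> int:
    """Penetration depth in the body at a transducer frequency, cm.

    Tabulated frequencies return the table cell; any other positive
    frequency snaps to the nearest tabulated frequency (ties towards the
    lower, deeper-penetrating frequency).  The table itself follows
    floor(40/f).
    """
    if freq_mhz <= 0:
        raise ValueError(f"frequency must be positive, got {freq_mhz}")
    if freq_mhz in PENETRATION_TABLE_CM:
        return PENETRATION_TABLE_CM[freq_mhz]
    nearest = min(PENETRATION_TABLE_CM, key=lambda f: (abs(f - freq_mhz), f))
    return PENETRATION_TABLE_CM[nearest]


def wall_thickness(fill_fraction: float) -> float:
    """Bladder wall thickness at a fill fraction, mm (5 mm empty → 3 mm full)."""
    if not 0.0 <= fill_fraction <= 1.0:
        raise ValueError("fill_fraction must lie in [0, 1]")
    return 5.0 - 2.0 * fill_fraction


# reflected energy fractions at the anterior wall; only the endpoints are
# physically pinned (near-total reflection when empty, 5% when full) — the
# interpolation between them is linear and swappable
_REFLECT_EMPTY = 0.999
_REFLECT_FULL = 0.05


def anterior_reflection_fraction(fill_fraction: float) -> float:
    """Fraction of incident *energy* reflected at the anterior wall."""
    if not 0.0 <= fill_fraction <= 1.0:
        raise ValueError("fill_fraction must lie in [0, 1]")
    return _REFLECT_EMPTY + fill_fraction * (_REFLECT_FULL - _REFLECT_EMPTY)


def tgc_gain(tof_us, freq_mhz: float, assumed_velocity: float = SOFT_TISSUE.velocity):
    """Time-gain-control gain at a time of flight, dB.

    The gain that exactly cancels soft-tissue absorption for an echo
    arriving at ``tof_us``: attenuation coefficient (dB/cm) times the
    one-way path length (cm) implied by the round-trip time.  Scalar or
    array ``tof_us``.
    """
    tof = np.asarray(tof_us, dtype=float)
    if np.any(tof < 0):
        raise ValueError("time of flight must be non-negative")
    depth_cm = 0.5 * tof * assumed_velocity * 1e-6 * 100.0  # µs × m/s → cm
    gain = attenuation_coeff(freq_mhz, SOFT_TISSUE) * depth_cm
    return float(gain) if np.isscalar(tof_us) else gain
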