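"""Synthetic A-mode echo generator with ground-truth labels.

This is the package's synthetic-data source: it produces single-element
pulse-echo (A-scan) traces from a layered tissue model over a parametric
bladder, and whole multi-day collection sessions in the style of a
home-monitoring protocol (a filling session per day, acquisitions at fixed
intervals, a handful of traces per acquisition).

The acoustic model is deliberately sparse: each interface contributes one
echo — a Gaussian-windowed sinusoid at the pulse frequency — whose amplitude
follows the energy budget of the anterior-wall reflection (near-total when
the bladder is empty, ≈5% when full) and soft-tissue absorption, with
time-gain control applied exactly as the feature extractor assumes it.
Multiplicative speckle perturbs echo amplitudes and additive Gaussian noise
models the post-amplifier receiver chain.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .physics import (
    MUSCLE,
    SOFT_TISSUE,
    URINE,
    BladderGeometry,
    MediumProperties,
    anterior_reflection_fraction,
    attenuation_coeff,
    penetration_depth,
    tgc_gain,
    time_of_flight,
    wall_thickness,
)
from .states import BladderState

__all__ = [
    "SubjectProfile",
    "SimulationConfig",
    "TraceTruth",
    "AScanTrace",
    "ProtocolDataset",
    "default_volunteers",
    "simulate_ascan",
    "fill_to_state",
    "fill_schedule",
    "simulate_protocol_dataset",
]

#: amplitude reflectivity of the urine/posterior-wall interface; near-total,
#: so a filling lumen returns a strong distal echo
POSTERIOR_REFLECT_AMP = 0.9


@dataclass(frozen=True)
class SubjectProfile:
    """Wearer covariates; BMI is always derived, never stored."""

    age: float
    sex: str  # "M" or "F"
    height_cm: float
    weight_kg: float
    subject_id: str = "S1"

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.sex not in ("M", "F"):
            raise ValueError("sex must be 'M' or 'F'")
        if self.height_cm <= 0 or self.weight_kg <= 0:
            raise ValueError("height and weight must be positive")

    @property
    def bmi(self) -> float:
        h_m = self.height_cm / 100.0
        return self.weight_kg / (h_m * h_m)


def default_volunteers() -> tuple[SubjectProfile, SubjectProfile]:
    """The two reference wearers: boys aged 6 (BMI 18.9) and 9 (BMI 23.4)."""
    v1 = SubjectProfile(age=6, sex="M", height_cm=115.0, weight_kg=25.0, subject_id="V1")
    v2 = SubjectProfile(age=9, sex="M", height_cm=135.0, weight_kg=42.65, subject_id="V2")
    return v1, v2


@dataclass(frozen=True)
class SimulationConfig:
    """Pulse, sampling and geometry parameters of the simulator.

    Defaults follow the reference hardware: 2.2 MHz single-element
    transducer, sub-25 ns excitation, 2 kHz pulse repetition frequency,
    20 cm region of interest.  ``fill_to_depth_gain`` maps fill fraction to
    lumen depth extent (mm per unit fill) — the bladder distends in depth
    first as it fills.
    """

    layer_stack: tuple[tuple[MediumProperties, float], ...] = ((MUSCLE, 40.0),)
    geometry_base: BladderGeometry = field(
        default_factory=lambda: BladderGeometry(
            anterior_wall_depth=40.0,
            fill_fraction=0.0,
            wall_thickness=5.0,
            lumen_depth_extent=0.0,
        )
    )
    fill_to_depth_gain: float = 60.0
    pulse_freq: float = 2.2
    pulse_duration_ns: float = 25.0
    prf_hz: float = 2000.0
    sample_rate: float = 10.0
    roi_depth: float = 200.0
    noise_sd: float = 0.05
    speckle_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.layer_stack or any(th <= 0 for _, th in self.layer_stack):
            raise ValueError("layer_stack thicknesses must all be positive")
        if self.sample_rate <= 2.0 * self.pulse_freq:
            raise ValueError("sample_rate must exceed twice the pulse frequency")
        # penetration table is in cm; the ROI may not exceed it
        if self.roi_depth > 10.0 * penetration_depth(self.pulse_freq):
            raise ValueError("roi_depth exceeds penetration at the pulse frequency")
        if self.noise_sd < 0 or self.speckle_sd < 0:
            raise ValueError("noise levels must be non-negative")

    @property
    def anterior_wall_depth(self) -> float:
        return float(sum(th for _, th in self.layer_stack))

    def geometry_at(self, fill_fraction: float) -> BladderGeometry:
        """Bladder geometry at a given fill fraction."""
        return BladderGeometry(
            anterior_wall_depth=self.anterior_wall_depth,
            fill_fraction=fill_fraction,
            wall_thickness=wall_thickness(fill_fraction),
            lumen_depth_extent=self.fill_to_depth_gain * fill_fraction,
        )


@dataclass(frozen=True)
class TraceTruth:
    """Ground truth carried alongside a simulated trace."""

    fill_fraction: float
    state: BladderState
    anterior_depth_mm: float
    posterior_depth_mm: float


@dataclass(frozen=True)
class AScanTrace:
    """A sampled pulse-echo amplitude trace.

    ``samples`` are in normalised arbitrary units (unit incident amplitude);
    ``sample_rate`` in MHz.  ``truth`` is present for simulated traces.
    """

    samples: np.ndarray
    sample_rate: float
    tgc_applied: bool = True
    truth: TraceTruth | None = None
    subject_ref: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace samples must be finite")

    @property
    def times_us(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate

    @property
    def full_scale(self) -> float:
        """A-scan height: maximum absolute amplitude of the trace."""
        return float(np.max(np.abs(self.samples))) if self.samples.size else 0.0


def fill_to_state(fill_fraction: float) -> BladderState:
    """Nearest of the four acquisition points {0, 1/2, 3/4, 1}; ties round up."""
    if not 0.0 <= fill_fraction <= 1.0:
        raise ValueError("fill_fraction must lie in [0, 1]")
    points = (0.0, 0.5, 0.75, 1.0)
    best = BladderState.EMPTY
    best_d = math.inf
    for state, p in zip(BladderState, points):
        d = abs(fill_fraction - p)
        if d < best_d or (d == best_d and state > best):
            best, best_d = state, d
    return best


def _anterior_tof_us(config: SimulationConfig) -> float:
    return float(sum(time_of_flight(th, m.velocity) for m, th in config.layer_stack))


def _echo_budget(config: SimulationConfig, fill: float):
    """Arrival times, amplitudes and attenuations of the two wall echoes.

    Returns (tof_ant, amp_ant, tof_post, amp_post) with absorption applied
    but before TGC and noise.  Amplitudes are square roots of energy
    fractions; the posterior echo crosses the anterior interface twice, so
    its amplitude carries the full transmitted energy fraction (1 − R).
    """
    geom = config.geometry_at(fill)
    tof_ant = _anterior_tof_us(config)
    inner_mm = geom.wall_thickness + geom.lumen_depth_extent
    tof_post = tof_ant + time_of_flight(inner_mm, URINE.velocity)

    refl = anterior_reflection_fraction(fill)
    # one-way-path absorption in dB (round-trip convention, cancelled by TGC)
    att_ant_db = sum(
        attenuation_coeff(config.pulse_freq, m) * th / 10.0 for m, th in config.layer_stack
    )
    att_post_db = att_ant_db + (
        attenuation_coeff(config.pulse_freq, SOFT_TISSUE) * geom.wall_thickness / 10.0
        + attenuation_coeff(config.pulse_freq, URINE) * geom.lumen_depth_extent / 10.0
    )
    amp_ant = math.sqrt(refl) * 10.0 ** (-att_ant_db / 20.0)
    amp_post = (1.0 - refl) * POSTERIOR_REFLECT_AMP * 10.0 ** (-att_post_db / 20.0)
    return tof_ant, amp_ant, tof_post, amp_post


def simulate_ascan(
    config: SimulationConfig,
    fill_fraction: float,
    profile: SubjectProfile,
    seed: int | None = None,
) -> AScanTrace:
    """Simulate one A-scan at a given fill fraction.

    Deterministic for a fixed seed (``config.seed`` when ``seed`` is None).
    The trace window covers the round trip to ``roi_depth`` at the
    soft-tissue velocity; TGC is applied, then receiver noise is added.
    """
    if not 0.0 <= fill_fraction <= 1.0:
        raise ValueError("fill_fraction must lie in [0, 1]")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    t_max = time_of_flight(config.roi_depth, SOFT_TISSUE.velocity)
    n = int(round(config.sample_rate * t_max)) + 1
    t = np.arange(n) / config.sample_rate

    tof_ant, amp_ant, tof_post, amp_post = _echo_budget(config, fill_fraction)

    sigma = 1.0 / config.pulse_freq  # pulse envelope width, µs (~2 carrier cycles FWHM)
    trace = np.zeros(n)
    for tof, amp in ((tof_ant, amp_ant), (tof_post, amp_post)):
        if config.speckle_sd > 0:
            amp *= max(0.0, 1.0 + rng.normal(0.0, config.speckle_sd))
        dt = t - tof
        trace += amp * np.exp(-0.5 * (dt / sigma) ** 2) * np.cos(2.0 * np.pi * config.pulse_freq * dt)

    trace *= 10.0 ** (tgc_gain(t, config.pulse_freq, SOFT_TISSUE.velocity) / 20.0)
    if config.noise_sd > 0:
        trace += rng.normal(0.0, config.noise_sd, n)

    geom = config.geometry_at(fill_fraction)
    truth = TraceTruth(
        fill_fraction=fill_fraction,
        state=fill_to_state(fill_fraction),
        anterior_depth_mm=geom.anterior_wall_depth,
        posterior_depth_mm=geom.posterior_wall_depth,
    )
    return AScanTrace(
        samples=trace,
        sample_rate=config.sample_rate,
        tgc_applied=True,
        truth=truth,
        subject_ref=profile.subject_id,
    )


# fill boundaries between neighbouring states (ties round up at the exact
# boundary), and the acquisition-index → fill map that samples the four
# states equally while rising monotonically from 0 to 1
_CLASS_BOUNDS = (0.0, 0.25, 0.625, 0.875, 1.0)
_UNIFORM_BOUNDS = (0.0, 0.25, 0.5, 0.75, 1.0)


def fill_schedule(n_acquisitions: int) -> np.ndarray:
    """Monotone fill fractions for a session's acquisitions.

    Maps an even grid through the class-boundary quantiles so each of the
    four states receives (nearly) the same number of acquisitions, mirroring
    the roughly balanced class counts of the reference collection protocol.
    """
    if n_acquisitions < 1:
        raise ValueError("need at least one acquisition")
    if n_acquisitions == 1:
        return np.array([0.0])
    u = np.arange(n_acquisitions) / (n_acquisitions - 1)
    return np.interp(u, _UNIFORM_BOUNDS, _CLASS_BOUNDS)


@dataclass
class ProtocolDataset:
    """Labelled traces plus the extracted feature table for a protocol run."""

    traces: list[AScanTrace]
    features: pd.DataFrame
    summary: pd.DataFrame  # per-day sample counts and class balance


def simulate_protocol_dataset(
    config: SimulationConfig,
    profile: SubjectProfile,
    n_days: int = 5,
    session_duration_min: float = 160.0,
    interval_min: float = 10.0,
    samples_per_acquisition: int = 19,
    seed: int | None = None,
    gates=None,
) -> ProtocolDataset:
    """Simulate a multi-day collection protocol for one wearer.

    Each day is one filling session: the bladder fills monotonically from
    empty to full over ``session_duration_min``, traces are acquired in
    blocks of ``samples_per_acquisition`` every ``interval_min`` minutes and
    labelled by the nearest reference state.  Defaults give 16 acquisitions
    × 19 traces ≈ 300 samples/day, the order of the reference protocol.
    """
    if n_days < 1:
        raise ValueError("n_days must be at least 1")
    if samples_per_acquisition < 1:
        raise ValueError("samples_per_acquisition must be at least 1")
    from .features import GateConfig, extract_feature_table  # local import: avoids cycle

    if gates is None:
        gates = GateConfig()
    base_seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(base_seed)

    n_acq = 1 if interval_min <= 0 else max(1, int(session_duration_min // interval_min))
    fills = fill_schedule(n_acq)

    traces: list[AScanTrace] = []
    rows = []
    child_seeds = ss.generate_state(n_days * n_acq * samples_per_acquisition) >> 1
    k = 0
    for day in range(1, n_days + 1):
        day_states = []
        for fill in fills:
            for _ in range(samples_per_acquisition):
                tr = simulate_ascan(config, float(fill), profile, seed=int(child_seeds[k]))
                k += 1
                traces.append(tr)
                day_states.append(tr.truth.state)
        counts = {s.label: day_states.count(s) for s in BladderState}
        rows.append({"subject": profile.subject_id, "day": day, "samples": len(day_states), **counts})

    summary = pd.DataFrame(rows)
    features = extract_feature_table(traces, gates, profile)
    return ProtocolDataset(traces=traces, features=features, summary=summary)
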