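"""Two-gate echo detection and the 11-feature echo descriptor.

An A-scan is searched in two gates: gate A around the expected anterior
bladder wall and gate B beyond it for the posterior wall.  From the two
gated echoes the extractor derives times of flight T(A), T(B), distances
s(A), s(B) (piecewise media: the body velocity up to the first echo, the
urine velocity between the first and second), their differences ΔT and Δs,
amplitudes H(A), H(B) as percent of the A-scan height, relative levels
V = 20·log10(H/threshold) and ΔV — plus the wearer covariates BMI, sex and
age that contextualise them.

The body velocity is interpolated between muscle (1550 m/s, lean) and fat
(1436 m/s, high BMI) using standard BMI category endpoints; urine is fixed
at 1551 m/s.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .echo_sim import AScanTrace, SubjectProfile
from .physics import FAT, MUSCLE, URINE

__all__ = [
    "GateConfig",
    "GateEcho",
    "EchoFeatureVector",
    "FEATURE_TABLE_COLUMNS",
    "NO_ECHO_TIME_US",
    "NO_ECHO_DEPTH_MM",
    "NO_ECHO_HEIGHT_PCT",
    "BELOW_FLOOR_DB",
    "velocity_profile_for",
    "detect_gate_echo",
    "relative_level_db",
    "extract_features",
    "extract_feature_table",
]

# sentinels written when a gate returns no qualifying echo
NO_ECHO_TIME_US = 0.0
NO_ECHO_DEPTH_MM = 0.0
NO_ECHO_HEIGHT_PCT = 0.0
BELOW_FLOOR_DB = -120.0

#: fixed column order of the delimited-text feature table
FEATURE_TABLE_COLUMNS = [
    "t_a", "t_b", "s_a", "s_b", "dt", "ds",
    "h_a", "h_b", "v_a", "v_b", "dv",
    "bmi", "sex", "age", "state",
]

# BMI endpoints of the body-velocity interpolation (normal-weight lower
# bound and obesity threshold)
_BMI_LEAN = 18.5
_BMI_HIGH = 30.0


@dataclass(frozen=True)
class GateConfig:
    """Gate windows (depth, mm) and detection thresholds (fraction of full scale).

    ``gate_b_window`` may start at ``None``: the posterior gate then opens
    ``gate_b_offset_mm`` beyond wherever gate A fired, which tracks the
    anterior wall instead of assuming a fixed geometry.  The anterior
    threshold defaults lower than the posterior one because the anterior
    reflection weakens from near-total to ≈5% of the incident energy as the
    bladder fills while TGC boosts the distal echo; the anterior window ends
    at 60 mm so a mid-fill posterior wall cannot outbid the anterior echo
    under the max-amplitude rule.
    """

    gate_a_window: tuple[float, float] = (20.0, 60.0)
    gate_b_window: tuple[float | None, float] = (None, 200.0)
    threshold_a: float = 0.05
    threshold_b: float = 0.2
    gate_b_offset_mm: float = 2.0

    def __post_init__(self) -> None:
        a0, a1 = self.gate_a_window
        b0, b1 = self.gate_b_window
        if not a0 < a1:
            raise ValueError("gate A window must be ordered")
        if b0 is not None and not (b0 < b1 and b0 >= a1):
            raise ValueError("gate B window must be ordered and after gate A")
        for thr in (self.threshold_a, self.threshold_b):
            if not 0.0 < thr < 1.0:
                raise ValueError("thresholds must lie in (0, 1)")
        if self.gate_b_offset_mm <= 0:
            raise ValueError("gate_b_offset_mm must be positive")


@dataclass(frozen=True)
class GateEcho:
    """A detected gated echo: round-trip time (µs) and height (% of A-scan height)."""

    tof_us: float
    height_pct: float


@dataclass(frozen=True)
class EchoFeatureVector:
    """The 11 gate-derived echo features plus wearer covariates.

    Identities dt = t_b − t_a, ds = s_b − s_a and dv = v_b − v_a hold
    whenever both gates fire; when gate B is silent the B-side fields hold
    the no-echo sentinels and the Δ features are 0.  ``misplaced`` flags a
    trace in which even gate A found no echo (transducer off target).
    """

    t_a: float
    t_b: float
    s_a: float
    s_b: float
    dt: float
    ds: float
    h_a: float
    h_b: float
    v_a: float
    v_b: float
    dv: float
    bmi: float
    sex: str
    age: float
    misplaced: bool = False

    @property
    def gate_b_fired(self) -> bool:
        return not self.misplaced and self.v_b > BELOW_FLOOR_DB


def velocity_profile_for(profile: SubjectProfile) -> tuple[float, float]:
    """(body velocity, urine velocity) in m/s for a wearer.

    Body velocity runs linearly from muscle (1550) at BMI ≤ 18.5 to fat
    (1436) at BMI ≥ 30; urine is fixed at 1551.
    """
    bmi = profile.bmi
    if bmi <= _BMI_LEAN:
        body = MUSCLE.velocity
    elif bmi >= _BMI_HIGH:
        body = FAT.velocity
    else:
        frac = (bmi - _BMI_LEAN) / (_BMI_HIGH - _BMI_LEAN)
        body = MUSCLE.velocity + frac * (FAT.velocity - MUSCLE.velocity)
    return body, URINE.velocity


def _detect_in_time_window(
    trace: AScanTrace, t_window_us: tuple[float, float], threshold: float
) -> GateEcho | None:
    """Maximum-amplitude local peak of |trace| inside a time window.

    Returns None when no local peak reaches ``threshold`` × full scale.
    """
    if trace.samples.size == 0:
        raise ValueError("empty trace")
    full_scale = trace.full_scale
    if full_scale == 0.0:
        return None
    env = np.abs(trace.samples)
    peaks, _ = find_peaks(env)
    if peaks.size == 0:
        return None
    t = trace.times_us[peaks]
    amp = env[peaks]
    lo, hi = t_window_us
    ok = (t >= lo) & (t <= hi) & (amp >= threshold * full_scale)
    if not np.any(ok):
        return None
    idx = np.flatnonzero(ok)
    best = idx[np.argmax(amp[idx])]  # argmax takes the earliest on exact ties
    return GateEcho(tof_us=float(t[best]), height_pct=100.0 * float(amp[best]) / full_scale)


def detect_gate_echo(
    trace: AScanTrace,
    window_mm: tuple[float, float],
    threshold: float,
    velocity: float = MUSCLE.velocity,
) -> GateEcho | None:
    """Detect the gated echo in a depth window (mm), mapped to time at ``velocity``."""
    lo, hi = window_mm
    if not 0.0 <= lo < hi:
        raise ValueError("gate window must be ordered and non-negative")
    c = velocity * 1e-3  # mm/µs
    return _detect_in_time_window(trace, (2.0 * lo / c, 2.0 * hi / c), threshold)


def relative_level_db(h_pct: float, threshold_pct: float) -> float:
    """Relative signal level V = 20·log10(H/threshold), dB.

    Non-positive heights are below any threshold; they return the
    below-floor sentinel (−120 dB) rather than −inf.
    """
    if threshold_pct <= 0:
        raise ValueError("threshold must be positive")
    if h_pct <= 0:
        return BELOW_FLOOR_DB
    return 20.0 * np.log10(h_pct / threshold_pct)


def extract_features(
    trace: AScanTrace, gates: GateConfig, profile: SubjectProfile
) -> EchoFeatureVector:
    """Compute the echo feature vector of one trace.

    Gate A is searched at the body velocity; gate B opens just beyond the
    detected anterior echo and is mapped through the urine velocity, since
    the second interface sits across the lumen.  A silent gate A marks the
    vector ``misplaced`` (no anterior wall in the window — the garment check
    consumes this).  A silent gate B leaves the B-side at the no-echo
    sentinels with zero Δ features, the signature of an empty bladder.
    """
    body_v, urine_v = velocity_profile_for(profile)
    echo_a = detect_gate_echo(trace, gates.gate_a_window, gates.threshold_a, body_v)
    covs = dict(bmi=profile.bmi, sex=profile.sex, age=profile.age)
    if echo_a is None:
        return EchoFeatureVector(
            t_a=NO_ECHO_TIME_US, t_b=NO_ECHO_TIME_US,
            s_a=NO_ECHO_DEPTH_MM, s_b=NO_ECHO_DEPTH_MM,
            dt=0.0, ds=0.0,
            h_a=NO_ECHO_HEIGHT_PCT, h_b=NO_ECHO_HEIGHT_PCT,
            v_a=BELOW_FLOOR_DB, v_b=BELOW_FLOOR_DB, dv=0.0,
            misplaced=True, **covs,
        )

    t_a = echo_a.tof_us
    s_a = 0.5 * t_a * body_v * 1e-3
    h_a = echo_a.height_pct
    v_a = relative_level_db(h_a, 100.0 * gates.threshold_a)

    c_urine = urine_v * 1e-3  # mm/µs
    b_start_mm, b_end_mm = gates.gate_b_window
    if b_start_mm is None:
        t_lo = t_a + 2.0 * gates.gate_b_offset_mm / c_urine
    else:
        t_lo = max(t_a, t_a + 2.0 * (b_start_mm - s_a) / c_urine)
    t_hi = t_a + 2.0 * max(0.0, b_end_mm - s_a) / c_urine
    echo_b = _detect_in_time_window(trace, (t_lo, t_hi), gates.threshold_b)

    if echo_b is None:
        return EchoFeatureVector(
            t_a=t_a, t_b=NO_ECHO_TIME_US, s_a=s_a, s_b=NO_ECHO_DEPTH_MM,
            dt=0.0, ds=0.0, h_a=h_a, h_b=NO_ECHO_HEIGHT_PCT,
            v_a=v_a, v_b=BELOW_FLOOR_DB, dv=0.0, **covs,
        )

    t_b = echo_b.tof_us
    s_b = s_a + 0.5 * (t_b - t_a) * c_urine  # mm
    h_b = echo_b.height_pct
    v_b = relative_level_db(h_b, 100.0 * gates.threshold_b)
    return EchoFeatureVector(
        t_a=t_a, t_b=t_b, s_a=s_a, s_b=s_b,
        dt=t_b - t_a, ds=s_b - s_a,
        h_a=h_a, h_b=h_b, v_a=v_a, v_b=v_b, dv=v_b - v_a,
        **covs,
    )


def extract_feature_table(
    traces, gates: GateConfig, profile: SubjectProfile
) -> pd.DataFrame:
    """Feature table (fixed column order) for a collection of labelled traces.

    The ``state`` column is the truth label carried by simulated traces;
    traces without truth get an empty state.  Misplaced vectors are kept and
    flagged via a boolean ``misplaced`` helper column (not part of the
    on-disk format).
    """
    rows = []
    for tr in traces:
        fv = extract_features(tr, gates, profile)
        row = {k: getattr(fv, k) for k in FEATURE_TABLE_COLUMNS[:-1]}
        row["state"] = tr.truth.state.label if tr.truth is not None else ""
        row["misplaced"] = fv.misplaced
        rows.append(row)
    return pd.DataFrame(rows, columns=FEATURE_TABLE_COLUMNS + ["misplaced"])
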