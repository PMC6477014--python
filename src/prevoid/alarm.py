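"""Pre-void alarm policy: triggering, garment check, self-tuning, monitoring.

The policy fires a pre-void alarm whenever the voted bladder state reaches
its triggering point (3/4 by default — the state at which the urge to void
typically begins).  A moisture sensor closes the loop: a wet event with no
preceding pre-void alarm means the trigger was too late and is lowered one
step; a wet event despite a prior alarm means the alarm modality failed to
wake the wearer, so the policy escalates to the next modality instead.
Garment placement is verified against an empty-bladder echo signature
captured at calibration.  Third-party notification is a log event only.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

from .echo_sim import AScanTrace, SubjectProfile
from .features import EchoFeatureVector, GateConfig, extract_features
from .models import TrainedModelSet, predict_states, vote
from .states import BladderState

__all__ = [
    "DEFAULT_MODALITIES",
    "AlarmPolicy",
    "Event",
    "EventLog",
    "alarm_decision",
    "garment_check",
    "self_tune",
    "monitor_stream",
]

DEFAULT_MODALITIES = ("sound", "vibration", "speech")

#: minutes between alarms (prevents alarm storms) and the window within
#: which a pre-void alarm counts as "prior" to a moisture event
DEFAULT_REFRACTORY_MIN = 10.0
DEFAULT_LOOKBACK_MIN = 15.0


@dataclass(frozen=True)
class AlarmPolicy:
    """Triggering state, alarm modalities and escalation level."""

    trigger_state: BladderState = BladderState.THREE_QUARTERS
    modalities: tuple[str, ...] = DEFAULT_MODALITIES
    escalation_level: int = 0
    notify_third_party: bool = False

    def __post_init__(self) -> None:
        if self.trigger_state not in (BladderState.HALF, BladderState.THREE_QUARTERS):
            raise ValueError("trigger_state must be 1/2 or 3/4")
        if not self.modalities:
            raise ValueError("at least one alarm modality is required")
        if not 0 <= self.escalation_level < len(self.modalities):
            raise ValueError("escalation_level out of range")

    @property
    def modality(self) -> str:
        return self.modalities[self.escalation_level]


@dataclass(frozen=True)
class Event:
    """One timestamped log entry."""

    time_min: float
    kind: str  # prevoid_alarm | moisture | state_estimate | garment_fault | notification
    payload: dict = field(default_factory=dict)

    _KINDS = ("prevoid_alarm", "moisture", "state_estimate", "garment_fault", "notification")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown event kind: {self.kind!r}")


class EventLog:
    """Append-only event list with non-decreasing timestamps."""

    def __init__(self, events=()) -> None:
        self.events: list[Event] = []
        for e in events:
            self.append(e)

    def append(self, event: Event) -> None:
        if self.events and event.time_min < self.events[-1].time_min:
            raise ValueError("event timestamps must be non-decreasing")
        self.events.append(event)

    def of_kind(self, kind: str) -> list[Event]:
        return [e for e in self.events if e.kind == kind]

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)


def alarm_decision(state: BladderState, policy: AlarmPolicy, time_min: float = 0.0) -> Event | None:
    """Emit a pre-void alarm event iff ``state`` is at or above the trigger."""
    if BladderState(state) < policy.trigger_state:
        return None
    return Event(
        time_min=time_min,
        kind="prevoid_alarm",
        payload={
            "state": BladderState(state).label,
            "modality": policy.modality,
            "notify_third_party": policy.notify_third_party,
        },
    )


def garment_check(
    trace: AScanTrace,
    empty_signature: EchoFeatureVector,
    tolerance: tuple[float, float] = (5.0, 20.0),
    gates: GateConfig | None = None,
    profile: SubjectProfile | None = None,
) -> bool:
    """True when the garment is worn correctly.

    The trace is compared against the empty-bladder calibration signature:
    gate A must fire and its (time of flight, height) must lie within
    ``tolerance`` = (µs, % of A-scan height) of the signature.
    """
    if gates is None:
        gates = GateConfig()
    if profile is None:
        raise ValueError("a subject profile is required to extract features")
    fv = extract_features(trace, gates, profile)
    if fv.misplaced:
        return False
    tol_t, tol_h = tolerance
    return abs(fv.t_a - empty_signature.t_a) <= tol_t and abs(fv.h_a - empty_signature.h_a) <= tol_h


def self_tune(
    policy: AlarmPolicy, log: EventLog, lookback_min: float = DEFAULT_LOOKBACK_MIN
) -> AlarmPolicy:
    """Adjust the policy from the night's moisture feedback.

    A moisture event with no pre-void alarm in the preceding
    ``lookback_min`` minutes lowers the trigger one step (3/4 → 1/2, never
    below); a moisture event with a prior alarm keeps the trigger and
    escalates the modality (capped at the last one).  No moisture events —
    unchanged policy.
    """
    moistures = log.of_kind("moisture")
    if not moistures:
        return policy
    alarms = [e.time_min for e in log.of_kind("prevoid_alarm")]
    missed = any(
        not any(m.time_min - lookback_min <= t <= m.time_min for t in alarms) for m in moistures
    )
    if missed:
        lowered = max(BladderState.HALF, BladderState(int(policy.trigger_state) - 1))
        return replace(policy, trigger_state=BladderState(lowered))
    bumped = min(policy.escalation_level + 1, len(policy.modalities) - 1)
    return replace(policy, escalation_level=bumped)


def monitor_stream(
    timed_traces,
    models: TrainedModelSet,
    gates: GateConfig,
    policy: AlarmPolicy,
    profile: SubjectProfile,
    empty_signature: EchoFeatureVector | None = None,
    moisture_times=(),
    refractory_min: float = DEFAULT_REFRACTORY_MIN,
    lookback_min: float = DEFAULT_LOOKBACK_MIN,
) -> tuple[EventLog, AlarmPolicy]:
    """Run the monitoring loop over a night's traces.

    ``timed_traces`` is an iterable of (time in minutes, trace) in time
    order.  The first trace doubles as the garment check when an
    ``empty_signature`` is given; a misplaced garment aborts the session
    with a single garment_fault event.  Per trace: features → three
    classifier opinions → vote → alarm decision (at most one alarm per
    ``refractory_min``).  Moisture events are merged in and self-tuning is
    applied at session end; returns the log and the updated policy.
    """
    timed_traces = list(timed_traces)
    log = EventLog()
    if not timed_traces:
        return log, policy

    t0, first = timed_traces[0]
    if empty_signature is not None and not garment_check(
        first, empty_signature, gates=gates, profile=profile
    ):
        log.append(Event(time_min=t0, kind="garment_fault", payload={}))
        return log, policy

    pending = sorted(float(t) for t in moisture_times)
    last_alarm = -float("inf")
    for t, trace in timed_traces:
        while pending and pending[0] <= t:
            log.append(Event(time_min=pending.pop(0), kind="moisture", payload={}))
        opinions = predict_states(models, extract_features(trace, gates, profile))
        state = vote(opinions)
        log.append(
            Event(time_min=t, kind="state_estimate", payload={"state": state.label})
        )
        ev = alarm_decision(state, policy, time_min=t)
        if ev is not None and t - last_alarm >= refractory_min:
            log.append(ev)
            last_alarm = t
            if policy.notify_third_party:
                log.append(Event(time_min=t, kind="notification", payload={"to": "carer"}))
    for t in pending:
        log.append(Event(time_min=t, kind="moisture", payload={}))
    return log, self_tune(policy, log, lookback_min=lookback_min)
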