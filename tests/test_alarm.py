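import dataclasses

import numpy as np
import pytest

from prevoid.alarm import (
    AlarmPolicy,
    Event,
    EventLog,
    alarm_decision,
    garment_check,
    monitor_stream,
    self_tune,
)
from prevoid.echo_sim import AScanTrace, SimulationConfig, simulate_ascan
from prevoid.features import GateConfig, extract_features
from prevoid.models import train_models
from prevoid.states import BladderState

E, H, T, F = BladderState


@pytest.fixture(scope="module")
def trained(small_dataset):
    return train_models(small_dataset, small_dataset["state"], seed=0)


@pytest.fixture(scope="module")
def sim_cfg():
    return SimulationConfig(noise_sd=0.02, speckle_sd=0.02)


@pytest.fixture(scope="module")
def empty_signature(sim_cfg, gates, volunteers):
    tr = simulate_ascan(sim_cfg, 0.0, volunteers[0], seed=900)
    return extract_features(tr, gates, volunteers[0])


@pytest.mark.parametrize(
    "state,trigger,fires",
    [(T, T, True), (H, T, False), (F, H, True), (F, T, True), (E, H, False)],
)
def test_alarm_fires_iff_state_reaches_trigger(state, trigger, fires):
    policy = AlarmPolicy(trigger_state=trigger)
    ev = alarm_decision(state, policy, time_min=1.0)
    assert (ev is not None) == fires
    if fires:
        assert ev.kind == "prevoid_alarm" and ev.payload["modality"] == "sound"


def test_alarm_decision_is_monotone_in_state():
    policy = AlarmPolicy()
    fired = [alarm_decision(s, policy) is not None for s in BladderState]
    assert fired == sorted(fired)


def test_garment_check_accepts_signature_and_rejects_shift(
    sim_cfg, gates, volunteers, empty_signature
):
    v1 = volunteers[0]
    same = simulate_ascan(sim_cfg, 0.0, v1, seed=901)
    assert garment_check(same, empty_signature, gates=gates, profile=v1)
    # anterior wall shifted +20 mm: outside the (5 µs, 20 %) tolerance
    stack = ((sim_cfg.layer_stack[0][0], 60.0),)
    shifted_cfg = dataclasses.replace(sim_cfg, layer_stack=stack)
    shifted = simulate_ascan(shifted_cfg, 0.0, v1, seed=902)
    assert not garment_check(shifted, empty_signature, gates=gates, profile=v1)
    # pure noise: gate A never fires
    noise = AScanTrace(samples=np.full(2000, 1e-9), sample_rate=10.0)
    assert not garment_check(noise, empty_signature, gates=gates, profile=v1)


def test_self_tune_rules():
    policy = AlarmPolicy(trigger_state=T)
    missed = EventLog([Event(0.0, "moisture")])
    assert self_tune(policy, missed).trigger_state is H
    heard = EventLog([Event(0.0, "prevoid_alarm"), Event(5.0, "moisture")])
    tuned = self_tune(policy, heard)
    assert tuned.trigger_state is T and tuned.escalation_level == 1
    assert self_tune(policy, EventLog()) == policy


def test_self_tune_respects_bounds():
    low = self_tune(AlarmPolicy(trigger_state=H), EventLog([Event(0.0, "moisture")]))
    assert low.trigger_state is H  # never below 1/2
    maxed = AlarmPolicy(escalation_level=2)
    log = EventLog([Event(0.0, "prevoid_alarm"), Event(1.0, "moisture")])
    assert self_tune(maxed, log).escalation_level == 2  # capped at last modality


def test_self_tune_lookback_window():
    # the alarm is too old to count as "prior" → treated as missed
    policy = AlarmPolicy(trigger_state=T)
    log = EventLog([Event(0.0, "prevoid_alarm"), Event(60.0, "moisture")])
    assert self_tune(policy, log, lookback_min=15.0).trigger_state is H


def test_event_log_enforces_time_order():
    log = EventLog([Event(1.0, "moisture")])
    with pytest.raises(ValueError):
        log.append(Event(0.5, "moisture"))


def _sweep(sim_cfg, volunteers, fills, spacing=5.0, seed0=500):
    v1 = volunteers[0]
    return [
        (i * spacing, simulate_ascan(sim_cfg, f, v1, seed=seed0 + i))
        for i, f in enumerate(fills)
    ]


def test_fill_sweep_raises_exactly_one_first_alarm(
    sim_cfg, gates, volunteers, trained, empty_signature
):
    """A monotone filling night alarms once, at/after the first 3/4 estimate."""
    timed = _sweep(sim_cfg, volunteers, np.linspace(0.0, 1.0, 13))
    log, _ = monitor_stream(
        timed, trained, gates, AlarmPolicy(), volunteers[0], empty_signature,
        refractory_min=1e9,  # isolate the first-alarm logic
    )
    alarms = log.of_kind("prevoid_alarm")
    assert len(alarms) == 1
    estimates = log.of_kind("state_estimate")
    first_34 = next(
        e.time_min for e in estimates
        if BladderState.from_label(e.payload["state"]) >= T
    )
    assert alarms[0].time_min >= first_34


def test_refractory_limits_alarm_rate(sim_cfg, gates, volunteers, trained):
    timed = _sweep(sim_cfg, volunteers, [1.0] * 8, spacing=5.0)
    log, _ = monitor_stream(
        timed, trained, gates, AlarmPolicy(), volunteers[0], refractory_min=10.0
    )
    times = [e.time_min for e in log.of_kind("prevoid_alarm")]
    assert len(times) >= 2
    assert all(b - a >= 10.0 for a, b in zip(times, times[1:]))


def test_empty_night_never_alarms(sim_cfg, gates, volunteers, trained, empty_signature):
    timed = _sweep(sim_cfg, volunteers, [0.0] * 6)
    log, _ = monitor_stream(
        timed, trained, gates, AlarmPolicy(), volunteers[0], empty_signature
    )
    assert not log.of_kind("prevoid_alarm")


def test_misplaced_garment_aborts_session(sim_cfg, gates, volunteers, trained, empty_signature):
    noise = AScanTrace(samples=np.full(2581, 1e-9), sample_rate=10.0)
    log, _ = monitor_stream(
        [(0.0, noise)], trained, gates, AlarmPolicy(), volunteers[0], empty_signature
    )
    assert [e.kind for e in log] == ["garment_fault"]


def test_missed_void_lowers_trigger_after_session(
    sim_cfg, gates, volunteers, trained, empty_signature
):
    timed = _sweep(sim_cfg, volunteers, [0.0] * 4)  # no alarm all night
    _, tuned = monitor_stream(
        timed, trained, gates, AlarmPolicy(), volunteers[0], empty_signature,
        moisture_times=[12.0],
    )
    assert tuned.trigger_state is H


def test_policy_invariants():
    with pytest.raises(ValueError):
        AlarmPolicy(trigger_state=BladderState.FULL)
    with pytest.raises(ValueError):
        AlarmPolicy(escalation_level=5)
    with pytest.raises(ValueError):
        Event(0.0, "explosion")
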