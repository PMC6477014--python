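"""Plumbing: feature tables, trace records, event logs and configuration.

Everything is plain text.  Feature tables are comma-delimited with a fixed
column order; a silent posterior gate is written as empty fields and mapped
back to the in-memory no-echo sentinels on load.  Traces are stored as a
commented metadata header followed by one sample per line.  Configuration
is a single YAML document with general (alarm), personal (wearer),
simulation, gate, CV and policy sections.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .alarm import DEFAULT_MODALITIES, AlarmPolicy, Event, EventLog
from .echo_sim import AScanTrace, SimulationConfig, SubjectProfile, TraceTruth
from .features import (
    BELOW_FLOOR_DB,
    FEATURE_TABLE_COLUMNS,
    NO_ECHO_DEPTH_MM,
    NO_ECHO_HEIGHT_PCT,
    NO_ECHO_TIME_US,
    GateConfig,
)
from .models import CVScheme
from .states import BladderState

__all__ = [
    "AppConfig",
    "FeatureTableError",
    "load_feature_table",
    "save_feature_table",
    "write_trace",
    "read_trace",
    "write_event_log",
    "read_event_log",
    "load_config",
]

logger = logging.getLogger("prevoid")

_SENTINELS = {
    "t_b": NO_ECHO_TIME_US,
    "s_b": NO_ECHO_DEPTH_MM,
    "h_b": NO_ECHO_HEIGHT_PCT,
    "v_b": BELOW_FLOOR_DB,
    "dt": 0.0,
    "ds": 0.0,
    "dv": 0.0,
}
_NUMERIC_COLUMNS = [c for c in FEATURE_TABLE_COLUMNS if c not in ("sex", "state")]


class FeatureTableError(ValueError):
    """Malformed feature table: names the offending row and column."""


def save_feature_table(table: pd.DataFrame, path) -> None:
    """Write a feature table; sentinel B-side fields become empty cells."""
    out = table.loc[:, FEATURE_TABLE_COLUMNS].copy()
    silent = out["v_b"] <= BELOW_FLOOR_DB
    for col in ("t_b", "s_b", "h_b", "v_b", "dt", "ds", "dv"):
        out[col] = out[col].astype(object)
        out.loc[silent, col] = ""
    out.to_csv(path, index=False)


def load_feature_table(path) -> tuple[pd.DataFrame, pd.Series]:
    """Read a feature table → (feature frame, state labels as BladderState).

    The header must match the fixed column order exactly; empty B-side
    fields map back to the no-echo sentinels; any non-numeric cell raises a
    :class:`FeatureTableError` naming the row and column.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(raw.columns) != FEATURE_TABLE_COLUMNS:
        raise FeatureTableError(
            f"bad header: expected {FEATURE_TABLE_COLUMNS}, got {list(raw.columns)}"
        )
    df = raw.copy()
    for col in _NUMERIC_COLUMNS:
        vals = []
        for i, cell in enumerate(raw[col]):
            if cell == "":
                if col in _SENTINELS:
                    vals.append(_SENTINELS[col])
                    continue
                raise FeatureTableError(f"empty cell at row {i}, column {col!r}")
            try:
                vals.append(float(cell))
            except ValueError:
                raise FeatureTableError(
                    f"non-numeric cell at row {i}, column {col!r}: {cell!r}"
                ) from None
        df[col] = vals
    try:
        labels = raw["state"].map(BladderState.from_label)
    except ValueError as exc:
        raise FeatureTableError(f"bad state label: {exc}") from None
    features = df.drop(columns=["state"])
    logger.info("loaded feature table %s: %d rows", path, len(features))
    return features, labels


def write_trace(trace: AScanTrace, path) -> None:
    """Serialise a trace: '# key: value' metadata header, one sample per line."""
    lines = [
        "# prevoid a-scan trace v1",
        f"# sample_rate_mhz: {trace.sample_rate!r}",
        f"# tgc_applied: {str(trace.tgc_applied).lower()}",
        f"# subject_ref: {trace.subject_ref}",
    ]
    if trace.truth is not None:
        lines += [
            f"# fill_fraction: {trace.truth.fill_fraction!r}",
            f"# state: {trace.truth.state.label}",
            f"# anterior_depth_mm: {trace.truth.anterior_depth_mm!r}",
            f"# posterior_depth_mm: {trace.truth.posterior_depth_mm!r}",
        ]
    body = "\n".join(f"{x:.9e}" for x in trace.samples)
    Path(path).write_text("\n".join(lines) + "\n" + body + "\n")


def read_trace(path) -> AScanTrace:
    """Read a trace record written by :func:`write_trace`."""
    meta: dict[str, str] = {}
    samples: list[float] = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            if ":" in line:
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
        elif line.strip():
            samples.append(float(line))
    truth = None
    if "state" in meta:
        truth = TraceTruth(
            fill_fraction=float(meta["fill_fraction"]),
            state=BladderState.from_label(meta["state"]),
            anterior_depth_mm=float(meta["anterior_depth_mm"]),
            posterior_depth_mm=float(meta["posterior_depth_mm"]),
        )
    return AScanTrace(
        samples=np.asarray(samples),
        sample_rate=float(meta["sample_rate_mhz"]),
        tgc_applied=meta.get("tgc_applied", "true") == "true",
        truth=truth,
        subject_ref=meta.get("subject_ref", ""),
    )


def write_event_log(log: EventLog, path) -> None:
    """Line-delimited events: time, kind, JSON payload (tab-separated)."""
    with open(path, "w") as fh:
        for e in log:
            fh.write(f"{e.time_min:.3f}\t{e.kind}\t{json.dumps(e.payload)}\n")


def read_event_log(path) -> EventLog:
    log = EventLog()
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        t, kind, payload = line.split("\t", 2)
        log.append(Event(time_min=float(t), kind=kind, payload=json.loads(payload)))
    return log


@dataclass
class AppConfig:
    """Resolved application configuration.

    BMI is derived from the personal height/weight, never stored.
    """

    general: dict = field(default_factory=lambda: {"n_alarms": 3, "speech": True})
    personal: SubjectProfile | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    gates: GateConfig = field(default_factory=GateConfig)
    cv: CVScheme = field(default_factory=CVScheme)
    policy: AlarmPolicy = field(default_factory=AlarmPolicy)
    seed: int = 0
    version: int = 1


def load_config(path) -> AppConfig:
    """Load a YAML config file into an :class:`AppConfig`.

    Unknown keys raise; sub-section invariants are enforced by the
    sub-config constructors themselves.
    """
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {"general", "personal", "simulation", "gates", "cv", "policy", "seed", "version"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = AppConfig()
    if "seed" in data:
        cfg.seed = int(data["seed"])
    if "version" in data:
        cfg.version = int(data["version"])
    if "general" in data:
        cfg.general = dict(data["general"])
    if "personal" in data:
        p = data["personal"]
        if "bmi" in p:
            raise ValueError("BMI is derived from height and weight; do not store it")
        cfg.personal = SubjectProfile(
            age=p["age"],
            sex=p["sex"],
            height_cm=p["height_cm"],
            weight_kg=p["weight_kg"],
            subject_id=p.get("subject_id", "S1"),
        )
    if "simulation" in data:
        cfg.simulation = dataclasses.replace(SimulationConfig(), **data["simulation"])
    if "gates" in data:
        g = dict(data["gates"])
        for key in ("gate_a_window", "gate_b_window"):
            if key in g:
                g[key] = tuple(g[key])
        cfg.gates = GateConfig(**g)
    if "cv" in data:
        cfg.cv = CVScheme(**data["cv"])
    if "policy" in data:
        p = dict(data["policy"])
        if "trigger_state" in p:
            p["trigger_state"] = BladderState.from_label(str(p["trigger_state"]))
        if "modalities" in p:
            p["modalities"] = tuple(p["modalities"])
        cfg.policy = AlarmPolicy(**p)
    logger.info("resolved config from %s (seed=%d)", path, cfg.seed)
    return cfg
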