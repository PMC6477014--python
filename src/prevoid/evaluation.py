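"""Confusion matrices, dataset splits and Se/Sp at alarm triggering points.

A confusion matrix here is oriented rows = predicted state, columns = true
state, in the order empty, 1/2, 3/4, full.  The alarm view of a matrix
binarises it at a triggering point g ∈ {1/2, 3/4}: a sample is *positive*
when its true state is at or above g, and a prediction *alarms* when the
predicted state is at or above g.  Sensitivity is the alarmed fraction of
positives, specificity the non-alarmed fraction of negatives.

The module ships the reference training confusion matrices of the original
two-wearer feasibility data collection (the raw recordings were never
released) so the summary Se/Sp table can be recomputed from first
principles.
"""
from __future__ import annotations

import io
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources

import numpy as np
import pandas as pd

from .states import STATE_LABELS, BladderState

__all__ = [
    "ConfusionMatrix",
    "TriggerPoint",
    "UndefinedRateError",
    "REFERENCE_CLASS_COUNTS",
    "reference_confusion_matrices",
    "reference_protocol_sessions",
    "split_by_class",
    "sensitivity_specificity",
    "round2",
    "build_report",
    "format_report",
]

#: per-state sample totals of the reference data collection
#: (empty, 1/2, 3/4, full)
REFERENCE_CLASS_COUNTS = (826, 844, 740, 680)


class UndefinedRateError(ZeroDivisionError):
    """Se or Sp requested with an empty positive or negative class."""


@dataclass(frozen=True)
class ConfusionMatrix:
    """4×4 predicted×true counts (rows predicted, columns true)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=int)
        if arr.shape != (4, 4):
            raise ValueError("confusion matrix must be 4×4")
        if np.any(arr < 0):
            raise ValueError("confusion-matrix counts must be non-negative")
        object.__setattr__(self, "counts", arr)

    @classmethod
    def from_predictions(cls, predicted, true) -> "ConfusionMatrix":
        m = np.zeros((4, 4), dtype=int)
        np.add.at(m, (np.asarray(predicted, int), np.asarray(true, int)), 1)
        return cls(m)

    @property
    def column_totals(self) -> np.ndarray:
        """True-class sample counts."""
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.total

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.counts, index=STATE_LABELS, columns=STATE_LABELS)
        with open(path, "w") as fh:
            fh.write("# rows: predicted state; columns: true state\n")
            df.to_csv(fh, index_label="state")

    @classmethod
    def from_csv(cls, path_or_buf) -> "ConfusionMatrix":
        df = pd.read_csv(path_or_buf, comment="#", index_col=0)
        if list(df.columns) != STATE_LABELS or list(df.index) != STATE_LABELS:
            raise ValueError("confusion-matrix file must name the four states in order")
        return cls(df.to_numpy())


@dataclass(frozen=True)
class TriggerPoint:
    """Alarm triggering state; only 1/2 and 3/4 are meaningful thresholds."""

    state: BladderState

    def __post_init__(self) -> None:
        if self.state not in (BladderState.HALF, BladderState.THREE_QUARTERS):
            raise ValueError("trigger must be the 1/2 or 3/4 state")

    @classmethod
    def from_label(cls, label: str) -> "TriggerPoint":
        return cls(BladderState.from_label(label))


def _read_fixture(name: str) -> ConfusionMatrix:
    text = resources.files("prevoid.data").joinpath(name).read_text()
    return ConfusionMatrix.from_csv(io.StringIO(text))


def reference_confusion_matrices() -> dict[str, ConfusionMatrix]:
    """The packaged reference training matrices, keyed smo/lr/eb/voting."""
    return {
        key: _read_fixture(f"confusion_{key}.csv")
        for key in ("smo", "lr", "eb", "voting")
    }


def reference_protocol_sessions() -> pd.DataFrame:
    """The reference collection protocol: one row per wearer-day session."""
    with resources.files("prevoid.data").joinpath("collection_sessions.csv").open("r") as fh:
        return pd.read_csv(fh)


def split_by_class(class_counts, test_fraction: float, seed: int | None = None):
    """Per-class train/test counts for a holdout split.

    Per class, test = nearest integer (half up) to fraction × count and
    train is the remainder.  The arithmetic is deterministic; ``seed`` is
    accepted for API symmetry with the samplers and unused here.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    counts = [int(c) for c in class_counts]
    if any(c < 0 for c in counts):
        raise ValueError("class counts must be non-negative")
    test = tuple(int(np.floor(c * test_fraction + 0.5)) for c in counts)
    train = tuple(c - t for c, t in zip(counts, test))
    return train, test


def sensitivity_specificity(cm: ConfusionMatrix, trigger: TriggerPoint) -> tuple[float, float]:
    """Raw (Se, Sp) of a confusion matrix at a triggering point.

    Se = alarmed positives / positives (true state ≥ trigger), Sp =
    non-alarmed negatives / negatives.  Raises
    :class:`UndefinedRateError` when either class is empty.
    """
    g = int(trigger.state)
    c = cm.counts
    positives = int(c[:, g:].sum())
    negatives = int(c[:, :g].sum())
    if positives == 0 or negatives == 0:
        raise UndefinedRateError("Se/Sp undefined: empty positive or negative class")
    se = float(c[g:, g:].sum()) / positives
    sp = float(c[:g, :g].sum()) / negatives
    return se, sp


def round2(x: float) -> float:
    """Round half-up to 2 decimals, the convention of the summary tables."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class EvaluationReport:
    """Per-classifier count/percentage tables plus the Se/Sp summary."""

    class_tables: dict[str, pd.DataFrame]
    se_sp: pd.DataFrame


def _class_table(cm: ConfusionMatrix) -> pd.DataFrame:
    """Counts and column percentages, one (count, pct) column pair per true class."""
    totals = cm.column_totals
    data = {}
    for j, label in enumerate(STATE_LABELS):
        data[(f"{label}:{totals[j]}", "#")] = cm.counts[:, j]
        data[(f"{label}:{totals[j]}", "%")] = [
            round2(100.0 * cm.counts[i, j] / totals[j]) if totals[j] else 0.0 for i in range(4)
        ]
    return pd.DataFrame(data, index=STATE_LABELS)


def build_report(matrices: dict[str, ConfusionMatrix], triggers=None) -> EvaluationReport:
    """Evaluation report over named matrices at the given triggering points."""
    if not matrices:
        raise ValueError("at least one confusion matrix is required")
    if triggers is None:
        triggers = (
            TriggerPoint(BladderState.THREE_QUARTERS),
            TriggerPoint(BladderState.HALF),
        )
    tables = {name: _class_table(cm) for name, cm in matrices.items()}
    rows = {}
    for name, cm in matrices.items():
        for trig in triggers:
            se, sp = sensitivity_specificity(cm, trig)
            rows[(name, trig.state.label)] = {"Se": round2(se), "Sp": round2(sp)}
    se_sp = pd.DataFrame(rows).T
    se_sp.index.names = ["scheme", "trigger"]
    return EvaluationReport(class_tables=tables, se_sp=se_sp)


def format_report(report: EvaluationReport) -> str:
    """Human-readable rendering of an evaluation report."""
    parts = []
    for name, table in report.class_tables.items():
        parts.append(f"== {name} (rows predicted, columns true) ==")
        parts.append(table.to_string())
        parts.append("")
    parts.append("== Se/Sp at alarm triggering points ==")
    parts.append(report.se_sp.to_string())
    return "\n".join(parts)
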