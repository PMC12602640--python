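"""Replica decisions, threshold sweeps, and automation-threshold calibration.

A synthetic image is flagged as a replica when its decision variable falls
strictly below a threshold T (value < T → replica; value = T → non-replica).
The decision variable is the distance ratio at the image and feature levels
and the absolute converted segmentation value at the segmentation level.
Replica is the positive class throughout, so sensitivity reads as "fraction
of true replicas caught".
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "REPLICA",
    "NON_REPLICA",
    "GroundTruth",
    "SweepResult",
    "MarginThreshold",
    "AutomationResult",
    "read_ground_truth",
    "decide",
    "balanced_accuracy",
    "sweep_thresholds",
    "margin_threshold",
    "apply_automation",
]

REPLICA = "replica"
NON_REPLICA = "non-replica"

#: Likert visual scores mapping to the replica class (4-point scale, 3-4 = replica)
REPLICA_SCORE_MIN = 3


@dataclass(frozen=True)
class GroundTruth:
    """Binary replica labels per synthetic id, with free-text provenance."""

    labels: Mapping[str, str]
    provenance: str = ""

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.labels.items() if v not in (REPLICA, NON_REPLICA)}
        if bad:
            raise ValueError(f"non-binary ground-truth labels: {bad}")

    def classes_present(self) -> set[str]:
        return set(self.labels.values())

    def require_both_classes(self) -> None:
        present = self.classes_present()
        if present != {REPLICA, NON_REPLICA}:
            raise ValueError(
                f"ground truth must contain both classes; found only {sorted(present)}"
            )


def read_ground_truth(path: str | os.PathLike) -> GroundTruth:
    """Read ground truth from CSV.

    Two layouts are accepted: ``synthetic_id,label`` with labels
    replica/non-replica, or ``synthetic_id,rater1_score,rater2_score[,adjudicated]``
    with 4-point Likert scores where 3-4 means replica per rater. Rater
    disagreement requires an explicit ``adjudicated`` column (replica /
    non-replica); silent majority rules are refused.
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    if "label" in cols:
        labels = {str(r["synthetic_id"]): str(r["label"]) for _, r in df.iterrows()}
        return GroundTruth(labels=labels, provenance=f"labels from {path}")
    if {"rater1_score", "rater2_score"} <= cols:
        labels = {}
        for _, r in df.iterrows():
            sid = str(r["synthetic_id"])
            d1 = REPLICA if int(r["rater1_score"]) >= REPLICA_SCORE_MIN else NON_REPLICA
            d2 = REPLICA if int(r["rater2_score"]) >= REPLICA_SCORE_MIN else NON_REPLICA
            if d1 == d2:
                labels[sid] = d1
            else:
                adj = r.get("adjudicated")
                if not isinstance(adj, str) or adj not in (REPLICA, NON_REPLICA):
                    raise ValueError(
                        f"{sid}: raters disagree and no adjudicated label is given in {path}"
                    )
                labels[sid] = adj
        return GroundTruth(
            labels=labels,
            provenance=f"visual scores {REPLICA_SCORE_MIN}-4 -> replica, from {path}",
        )
    raise ValueError(
        f"{path}: expected columns (synthetic_id, label) or (synthetic_id, rater1_score, rater2_score)"
    )


def decide(value: float, threshold: float, decision_variable: str = "ratio") -> str:
    """Strict-inequality replica decision: replica iff value < threshold."""
    if decision_variable not in ("ratio", "absolute"):
        raise ValueError(f"decision_variable must be 'ratio' or 'absolute', got {decision_variable!r}")
    value = float(value)
    if value < 0:
        raise ValueError(f"decision variable must be >= 0, got {value}")
    return REPLICA if value < threshold else NON_REPLICA


def balanced_accuracy(predictions: Mapping[str, str], truth: GroundTruth) -> float:
    """(TPR + TNR) / 2 with replica as the positive class."""
    if set(predictions) != set(truth.labels):
        missing = set(truth.labels) ^ set(predictions)
        raise ValueError(f"prediction / truth id mismatch: {sorted(missing)}")
    truth.require_both_classes()
    tp = sum(1 for i, t in truth.labels.items() if t == REPLICA and predictions[i] == REPLICA)
    fn = sum(1 for i, t in truth.labels.items() if t == REPLICA and predictions[i] != REPLICA)
    tn = sum(1 for i, t in truth.labels.items() if t == NON_REPLICA and predictions[i] == NON_REPLICA)
    fp = sum(1 for i, t in truth.labels.items() if t == NON_REPLICA and predictions[i] != NON_REPLICA)
    return ((tp / (tp + fn)) + (tn / (tn + fp))) / 2.0


@dataclass(frozen=True)
class SweepResult:
    measure: str
    decision_variable: str
    grid: pd.DataFrame = field(repr=False)  # threshold, sensitivity, specificity, balanced_accuracy
    optimal_threshold: float
    optimal_balanced_accuracy: float


def sweep_thresholds(
    values: Mapping[str, float],
    truth: GroundTruth,
    step: float = 0.01,
    decision_variable: str = "ratio",
    measure: str = "",
    bounded: bool | None = None,
) -> SweepResult:
    """Evaluate the decision rule over a regular threshold grid.

    For ratio and other [0,1]-converted variables (``bounded``, the default
    for ratios and for converted similarities such as the Dice distance) the
    grid spans [0, 1] in ``step`` increments; for unconverted absolute
    variables (e.g. ASD in millimeters) it spans [0, max observed] in
    ``step``·max increments. The optimum maximizes balanced accuracy,
    smallest threshold on ties.
    """
    if step <= 0:
        raise ValueError(f"step must be > 0, got {step}")
    if decision_variable not in ("ratio", "absolute"):
        raise ValueError(f"unknown decision_variable {decision_variable!r}")
    truth.require_both_classes()
    if set(values) != set(truth.labels):
        raise ValueError("value ids must match ground-truth ids")
    vals = {k: float(v) for k, v in values.items()}
    if bounded is None:
        bounded = decision_variable == "ratio"
    n_steps = int(round(1.0 / step))
    if bounded:
        grid_points = np.linspace(0.0, 1.0, n_steps + 1)
    else:
        vmax = max(vals.values())
        grid_points = np.array([0.0]) if vmax == 0 else np.linspace(0.0, vmax, n_steps + 1)

    pos = [i for i, t in truth.labels.items() if t == REPLICA]
    neg = [i for i, t in truth.labels.items() if t == NON_REPLICA]
    pos_vals = np.array([vals[i] for i in pos])
    neg_vals = np.array([vals[i] for i in neg])
    rows = []
    for t in grid_points:
        sens = float(np.mean(pos_vals < t))
        spec = float(np.mean(neg_vals >= t))
        rows.append((float(t), sens, spec, (sens + spec) / 2.0))
    grid = pd.DataFrame(rows, columns=["threshold", "sensitivity", "specificity", "balanced_accuracy"])
    best = int(np.argmax(grid["balanced_accuracy"].to_numpy()))  # argmax takes first -> smallest T
    return SweepResult(
        measure=measure,
        decision_variable=decision_variable,
        grid=grid,
        optimal_threshold=float(grid.loc[best, "threshold"]),
        optimal_balanced_accuracy=float(grid.loc[best, "balanced_accuracy"]),
    )


@dataclass(frozen=True)
class MarginThreshold:
    """Margin-maximizing automation threshold with separability diagnostic."""

    threshold: float
    separable: bool
    replica_max: float
    non_replica_min: float


def margin_threshold(values: Mapping[str, float], truth: GroundTruth) -> MarginThreshold:
    """Mean of the highest replica value and the lowest non-replica value.

    This places the automation threshold mid-margin between the classes;
    ``separable`` is False when the classes overlap (replica max ≥
    non-replica min), in which case the midpoint is still returned but no
    threshold can be perfect.
    """
    truth.require_both_classes()
    if set(values) != set(truth.labels):
        raise ValueError("value ids must match ground-truth ids")
    rep_max = max(float(values[i]) for i, t in truth.labels.items() if t == REPLICA)
    non_min = min(float(values[i]) for i, t in truth.labels.items() if t == NON_REPLICA)
    return MarginThreshold(
        threshold=(rep_max + non_min) / 2.0,
        separable=rep_max < non_min,
        replica_max=rep_max,
        non_replica_min=non_min,
    )


@dataclass(frozen=True)
class AutomationResult:
    decisions: dict[str, str]
    flagged_count: int
    total: int


def apply_automation(values: Mapping[str, float], threshold: float,
                     decision_variable: str = "ratio") -> AutomationResult:
    """Apply a fixed threshold to a batch of decision variables."""
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    decisions = {i: decide(v, threshold, decision_variable) for i, v in values.items()}
    flagged = sum(1 for d in decisions.values() if d == REPLICA)
    return AutomationResult(decisions=decisions, flagged_count=flagged, total=len(decisions))
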