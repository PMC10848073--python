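"""Empirical ROC curves, tie-corrected AUC, and cutoff selection under a
specificity floor.

Candidate thresholds are the distinct observed marker values (positivity is
inclusive: value >= t under ``higher_positive``, value <= t under
``lower_positive``), plus a degenerate all-negative sentinel so the curve
spans (0,0) to (1,1) in (1-specificity, sensitivity) space. AUC is the
tie-corrected Mann-Whitney statistic U/(n_cases * n_controls), i.e. the
probability that a random case outranks a random control, with half credit
for ties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

ORIENTATIONS = ("higher_positive", "lower_positive")


@dataclass(frozen=True)
class OperatingPoint:
    """A single threshold with its achieved sensitivity and specificity."""

    threshold: float
    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC over the distinct observed thresholds.

    ``thresholds`` are ordered from the all-negative end (sentinel first)
    to the all-positive end; ``sensitivity``/``specificity`` align with them.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    orientation: str
    positive_class: str = "GC-resistant"

    def operating_points(self):
        return [
            OperatingPoint(float(t), float(se), float(sp))
            for t, se, sp in zip(self.thresholds, self.sensitivity, self.specificity)
        ]


def auc_mann_whitney(cases, controls, orientation: str = "higher_positive") -> float:
    """AUC as the tie-corrected Mann-Whitney statistic U/(n1*n2)."""
    cases = np.asarray(cases, dtype=float)
    controls = np.asarray(controls, dtype=float)
    _check_classes(cases, controls)
    if orientation not in ORIENTATIONS:
        raise ValueError(f"unknown orientation {orientation!r}")
    ranks = rankdata(np.concatenate([cases, controls]))
    r_cases = ranks[: cases.size].sum()
    u = r_cases - cases.size * (cases.size + 1) / 2.0
    auc = u / (cases.size * controls.size)
    return float(auc if orientation == "higher_positive" else 1.0 - auc)


def roc_curve(cases, controls, orientation: str = "higher_positive") -> RocCurve:
    """Build the empirical ROC from observed case and control marker values."""
    cases = np.asarray(cases, dtype=float)
    controls = np.asarray(controls, dtype=float)
    _check_classes(cases, controls)
    if orientation not in ORIENTATIONS:
        raise ValueError(f"unknown orientation {orientation!r}")

    values = np.unique(np.concatenate([cases, controls]))
    if orientation == "higher_positive":
        # sweep from all-negative (above max) down to all-positive
        thresholds = np.concatenate([[np.inf], values[::-1]])
        sens = np.array([np.mean(cases >= t) for t in thresholds])
        spec = np.array([np.mean(controls < t) for t in thresholds])
    else:
        thresholds = np.concatenate([[-np.inf], values])
        sens = np.array([np.mean(cases <= t) for t in thresholds])
        spec = np.array([np.mean(controls > t) for t in thresholds])
    return RocCurve(
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        auc=auc_mann_whitney(cases, controls, orientation),
        orientation=orientation,
    )


def infer_direction(cases, controls) -> str:
    """``up`` iff cases tend to exceed controls (AUC > 0.5 under
    higher_positive); ties break to ``up``."""
    return "up" if auc_mann_whitney(cases, controls, "higher_positive") >= 0.5 else "down"


def select_cutoff_at_specificity(curve: RocCurve, min_specificity: float) -> OperatingPoint:
    """Pick the threshold maximizing sensitivity subject to a specificity floor.

    Ties break toward higher specificity, then toward the more extreme
    threshold (larger under higher_positive, smaller under lower_positive).
    If no observed threshold meets the floor, returns the degenerate
    all-negative point (sensitivity 0, specificity 1) with a warning.
    """
    if not (0.0 < min_specificity < 1.0):
        raise ValueError("min_specificity must lie in (0, 1)")
    ok = curve.specificity >= min_specificity
    finite = np.isfinite(curve.thresholds)
    candidates = np.flatnonzero(ok & finite)
    if candidates.size == 0 or curve.sensitivity[candidates].max() == 0.0:
        logger.warning(
            "no threshold attains specificity >= %.3f with positive sensitivity; "
            "returning the degenerate all-negative operating point",
            min_specificity,
        )
        sentinel = float(curve.thresholds[0])
        return OperatingPoint(sentinel, 0.0, 1.0)
    sign = 1.0 if curve.orientation == "higher_positive" else -1.0
    best = max(
        candidates,
        key=lambda i: (
            curve.sensitivity[i],
            curve.specificity[i],
            sign * curve.thresholds[i],
        ),
    )
    return OperatingPoint(
        float(curve.thresholds[best]),
        float(curve.sensitivity[best]),
        float(curve.specificity[best]),
    )


def curve_to_frame(curve: RocCurve):
    """Export the ROC as a (threshold, sensitivity, specificity) table."""
    import pandas as pd

    return pd.DataFrame(
        {
            "threshold": curve.thresholds,
            "sensitivity": curve.sensitivity,
            "specificity": curve.specificity,
        }
    )


def _check_classes(cases: np.ndarray, controls: np.ndarray) -> None:
    if cases.size == 0 or controls.size == 0:
        raise ValueError("need at least one case and one control")
    if np.isnan(cases).any() or np.isnan(controls).any():
        raise ValueError("marker values must not contain NaN")
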