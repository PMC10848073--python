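"""Composite panel scoring: binarization, 0-12 score, score-level classifier.

Each of the 12 panel genes contributes one indicator bit: an up-gene (higher
relative expression in GC-resistant relapse) scores 1 when its Ct ratio is
greater than or equal to the cutoff; a down-gene scores 1 when the ratio is
strictly below the cutoff. The asymmetric inclusivity (>= vs <) is the
scoring contract and is preserved exactly. The composite score is the sum of
the bits (0-12); the score is then itself thresholded by ROC analysis under
a specificity floor to declare a patient GC-resistant.

The module also provides the exact Poisson-binomial distribution of the score
under per-gene independence, used as a closed-form oracle for the score's
distribution and AUC.

Two scikit-learn estimators expose this as fit/transform/predict:

``PanelBinarizer``
    transformer mapping an expression matrix to indicator bits; the panel
    (cutoff + direction per gene) is either supplied fixed or learned from
    labeled data by per-gene ROC cutoff selection.
``CompositeScoreClassifier``
    classifier summing the bits and thresholding the composite score, with
    the score cutoff learned by ROC under the specificity floor (or a fixed
    legacy real-valued cutoff applied as score >= ceil(c)).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .panel import validate_panel
from .roc import roc_curve, select_cutoff_at_specificity, infer_direction

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# functional core


def binarize(expr: pd.DataFrame, panel: pd.DataFrame):
    """Per-patient indicator bits against the panel cutoffs.

    Returns ``(bits, excluded)``: bits is a patients x genes 0/1 frame over
    the complete-case patients; ``excluded`` lists patients missing at least
    one panel gene (complete-case scoring, exclusions reported).
    """
    panel = validate_panel(panel.drop(columns="direction", errors="ignore"))
    missing_cols = [g for g in panel["gene"] if g not in expr.columns]
    if missing_cols:
        raise ValueError(f"expression matrix lacks panel genes: {missing_cols}")
    values = expr.loc[:, list(panel["gene"])]
    complete = values.notna().all(axis=1)
    excluded = list(values.index[~complete])
    if excluded:
        logger.warning("excluding %d patient(s) missing panel genes: %s",
                       len(excluded), excluded)
    values = values.loc[complete]
    bits = pd.DataFrame(index=values.index, columns=list(panel["gene"]), dtype=int)
    for _, row in panel.iterrows():
        v = values[row["gene"]].to_numpy(dtype=float)
        if row["direction"] == "up":
            bits[row["gene"]] = (v >= row["cutoff"]).astype(int)
        else:
            bits[row["gene"]] = (v < row["cutoff"]).astype(int)
    return bits, excluded


def composite_score(bits: pd.DataFrame) -> pd.Series:
    """Sum the indicator bits into the integer composite score (0..n_genes)."""
    arr = bits.to_numpy()
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("indicator bits must be 0/1")
    return pd.Series(arr.sum(axis=1), index=bits.index, name="score")


@dataclass(frozen=True)
class ScoreClassifierSummary:
    """Score-level cutoff with its operating point and AUC."""

    score_cutoff: float
    sensitivity: float
    specificity: float
    auc: float


def score_classifier(
    scores,
    labels,
    min_specificity: float = 0.80,
    legacy_cutoff: float | None = None,
    positive_label="resistant",
) -> ScoreClassifierSummary:
    """Characterize the composite score as a classifier of GC resistance.

    Builds the score ROC (integer thresholds, higher score = resistant) and
    selects the cutoff maximizing sensitivity under the specificity floor.
    A real-valued ``legacy_cutoff`` c is instead applied as score >= ceil(c).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive_label
    if pos.all() or (~pos).all():
        raise ValueError("both classes must be present to build the score ROC")
    cases, controls = scores[pos], scores[~pos]
    curve = roc_curve(cases, controls, "higher_positive")
    if legacy_cutoff is None:
        op = select_cutoff_at_specificity(curve, min_specificity)
        cutoff = op.threshold
        sens, spec = op.sensitivity, op.specificity
    else:
        cutoff = float(math.ceil(legacy_cutoff))
        sens = float(np.mean(cases >= cutoff))
        spec = float(np.mean(controls < cutoff))
    return ScoreClassifierSummary(cutoff, sens, spec, curve.auc)


# ---------------------------------------------------------------------------
# Poisson-binomial oracle


def poisson_binomial_pmf(probabilities) -> np.ndarray:
    """Exact pmf of a sum of independent Bernoulli(p_j) indicators.

    Iterative convolution (dynamic programming), O(n^2); support 0..n.
    """
    ps = np.asarray(probabilities, dtype=float)
    if np.any((ps < 0) | (ps > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    pmf = np.array([1.0])
    for p in ps:
        pmf = np.convolve(pmf, [1.0 - p, p])
    return pmf


def pmf_auc(pmf_cases: np.ndarray, pmf_controls: np.ndarray) -> float:
    """Closed-form AUC P(S_case > S_control) + 0.5 P(tie) between two pmfs."""
    cdf_controls = np.cumsum(pmf_controls)
    auc = 0.0
    for k, pk in enumerate(pmf_cases):
        below = cdf_controls[k - 1] if k > 0 else 0.0
        auc += pk * (below + 0.5 * pmf_controls[k] if k < len(pmf_controls) else below)
    return float(auc)


# ---------------------------------------------------------------------------
# scikit-learn estimators


class PanelBinarizer(TransformerMixin, BaseEstimator):
    """Map an expression matrix to per-gene resistance indicator bits.

    Parameters
    ----------
    panel : DataFrame or None
        Fixed panel (gene, cutoff, sensitivity, one_minus_specificity, auc).
        If None, the panel is learned from labeled training data: per gene,
        the scoring direction is inferred from the AUC orientation and the
        cutoff is chosen by ROC to maximize sensitivity at specificity
        >= ``min_specificity``.
    min_specificity : float
        Specificity floor used when learning cutoffs.
    positive_label : label of the GC-resistant class in ``y``.

    Attributes
    ----------
    panel_ : validated panel with ``direction`` column.
    excluded_ : patients dropped in the last ``transform`` (incomplete panel).
    """

    def __init__(self, panel=None, min_specificity: float = 0.80,
                 positive_label="resistant"):
        self.panel = panel
        self.min_specificity = min_specificity
        self.positive_label = positive_label

    def fit(self, X: pd.DataFrame, y=None):
        if self.panel is not None:
            self.panel_ = validate_panel(
                self.panel.drop(columns="direction", errors="ignore")
            )
            return self
        if y is None:
            raise ValueError("y is required to learn a panel from data")
        y = np.asarray(y)
        pos = y == self.positive_label
        rows = []
        for gene in X.columns:
            v = X[gene].to_numpy(dtype=float)
            cases, controls = v[pos], v[~pos]
            direction = infer_direction(cases, controls)
            orientation = "higher_positive" if direction == "up" else "lower_positive"
            curve = roc_curve(cases, controls, orientation)
            op = select_cutoff_at_specificity(curve, self.min_specificity)
            rows.append(
                {
                    "gene": gene,
                    "cutoff": op.threshold,
                    "sensitivity": op.sensitivity,
                    "one_minus_specificity": 1.0 - op.specificity,
                    "auc": curve.auc if direction == "up" else 1.0 - curve.auc,
                }
            )
        self.panel_ = validate_panel(pd.DataFrame(rows))
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "panel_")
        bits, excluded = binarize(X, self.panel_)
        self.excluded_ = excluded
        return bits


class CompositeScoreClassifier(ClassifierMixin, BaseEstimator):
    """Composite-score classifier of GC resistance.

    Sums the panel indicator bits into a 0-12 score and thresholds it; the
    score cutoff is selected on the training data by ROC under the
    specificity floor, unless a fixed ``legacy_cutoff`` c is given (applied
    as score >= ceil(c), since scores are integers).

    Attributes (after fit): ``panel_``, ``score_cutoff_``, ``sensitivity_``,
    ``specificity_``, ``auc_``, ``classes_``.
    """

    def __init__(self, panel=None, min_specificity: float = 0.80,
                 legacy_cutoff: float | None = None, positive_label="resistant"):
        self.panel = panel
        self.min_specificity = min_specificity
        self.legacy_cutoff = legacy_cutoff
        self.positive_label = positive_label

    def fit(self, X: pd.DataFrame, y):
        y = pd.Series(np.asarray(y), index=X.index)
        self.binarizer_ = PanelBinarizer(
            panel=self.panel,
            min_specificity=self.min_specificity,
            positive_label=self.positive_label,
        ).fit(X, y)
        self.panel_ = self.binarizer_.panel_
        bits = self.binarizer_.transform(X)
        scores = composite_score(bits)
        summary = score_classifier(
            scores,
            y.loc[bits.index],
            min_specificity=self.min_specificity,
            legacy_cutoff=self.legacy_cutoff,
            positive_label=self.positive_label,
        )
        self.score_cutoff_ = summary.score_cutoff
        self.sensitivity_ = summary.sensitivity
        self.specificity_ = summary.specificity
        self.auc_ = summary.auc
        self.classes_ = np.unique(y)
        return self

    def decision_function(self, X: pd.DataFrame) -> pd.Series:
        """Composite score per (complete-case) patient."""
        check_is_fitted(self, "score_cutoff_")
        return composite_score(self.binarizer_.transform(X))

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        scores = self.decision_function(X)
        negative = next(c for c in self.classes_ if c != self.positive_label)
        return np.where(scores >= self.score_cutoff_, self.positive_label, negative)
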