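"""Baseline group comparisons and the confounder-adjusted logistic model.

Group comparisons follow the clinical-baseline conventions: Pearson
chi-square without continuity correction for categorical variables,
two-sided Mann-Whitney U for continuous/ordinal ones. GC resistance is then
modeled by maximum-likelihood logistic regression (Newton/IRLS, Wald 95%
CIs) with the composite score entered alongside the clinical confounders:
age (years), female sex, disease duration (years), immunotherapy group
(ordinal 0/1/2 for none / mild-to-moderate / high efficacy), EDSS prior to
GC treatment, GC dose (mg), and optionally recruitment center (Bern=1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

IMMUNOTHERAPY_CODES = {"none": 0, "mild_to_moderate": 1, "high": 2}
ADJUSTMENT_COVARIATES = [
    "score", "female_sex", "age", "disease_duration",
    "immunotherapy_group", "edss_prior", "gc_dose_mg",
]


def chi_square_test(table) -> tuple[float, int, float]:
    """Pearson chi-square on an r x c contingency table, no Yates correction.

    Returns (statistic, degrees of freedom, p-value).
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or min(table.shape) < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    zero_rows = np.flatnonzero(table.sum(axis=1) == 0)
    zero_cols = np.flatnonzero(table.sum(axis=0) == 0)
    if zero_rows.size or zero_cols.size:
        raise ValueError(
            f"degenerate margins: zero rows {zero_rows.tolist()}, "
            f"zero columns {zero_cols.tolist()}"
        )
    res = sps.chi2_contingency(table, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U.

    Exact null enumeration for small tie-free samples (combined n <= 12),
    otherwise the normal approximation with tie correction. Returns
    (U of x over y, p-value).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    no_ties = np.unique(combined).size == combined.size
    method = "exact" if (combined.size <= 12 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class LogisticFit:
    """Adjusted logistic model: per-predictor ORs with Wald 95% CIs."""

    table: pd.DataFrame  # index predictor; coef, odds_ratio, ci_low, ci_high, p_value
    converged: bool
    n_obs: int
    log_likelihood: float

    def __post_init__(self):
        ok = (self.table["ci_low"] <= self.table["odds_ratio"] + 1e-12) & (
            self.table["odds_ratio"] <= self.table["ci_high"] + 1e-12
        )
        if not ok.all():
            raise ValueError("confidence intervals do not bracket the odds ratios")


class SeparationError(RuntimeError):
    """Perfect separation: the MLE does not exist."""


class CollinearityError(RuntimeError):
    """Rank-deficient design matrix."""


def encode_design(covariates: pd.DataFrame, scores: pd.Series,
                  include_center: bool = False) -> pd.DataFrame:
    """Fixed, documented encoding of the adjustment covariates.

    female_sex: female=1; immunotherapy_group: ordinal 0/1/2; center: Bern=1.
    The outcome column ``resistant`` is 1 for the GC-resistant group.
    """
    cov = covariates.set_index("patient_id").loc[scores.index]
    design = pd.DataFrame(index=scores.index)
    design["resistant"] = (cov["group"] == "resistant").astype(int)
    design["score"] = scores.astype(float)
    design["female_sex"] = (cov["sex"] == "female").astype(int)
    design["age"] = cov["age"].astype(float)
    design["disease_duration"] = cov["disease_duration"].astype(float)
    design["immunotherapy_group"] = cov["immunotherapy"].map(IMMUNOTHERAPY_CODES)
    if design["immunotherapy_group"].isna().any():
        raise ValueError("unknown immunotherapy category")
    design["edss_prior"] = cov["edss_prior"].astype(float)
    design["gc_dose_mg"] = cov["gc_dose_mg"].astype(float)
    if include_center:
        design["center"] = (cov["center"] == "bern").astype(int)
    return design


def fit_logistic(design: pd.DataFrame, outcome: str = "resistant",
                 predictors: list[str] | None = None) -> LogisticFit:
    """ML logistic regression with Wald standard errors and 95% CIs.

    Raises ``CollinearityError`` on a rank-deficient design and
    ``SeparationError`` on (quasi-)perfect separation; non-convergence is
    never returned silently.
    """
    if predictors is None:
        predictors = [c for c in design.columns if c != outcome]
    y = design[outcome].to_numpy(dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    X = design[predictors].to_numpy(dtype=float)
    if np.any(X.std(axis=0) == 0):
        const = [p for p, s in zip(predictors, X.std(axis=0)) if s == 0]
        raise ValueError(f"constant predictor(s): {const}")
    if len(y) <= len(predictors) + 1:
        raise ValueError("need more observations than predictors")
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise CollinearityError(
            f"design matrix is rank-deficient over predictors {predictors}"
        )
    model = sm.Logit(y, Xc)
    try:
        res = model.fit(disp=False, maxiter=200)
    except Exception as exc:  # statsmodels PerfectSeparationError
        if "separation" in str(exc).lower() or "Singular" in str(exc):
            raise SeparationError(str(exc)) from exc
        raise
    if not res.mle_retvals.get("converged", False):
        raise SeparationError("logistic fit did not converge (possible separation)")
    if np.abs(res.params).max() > 50:
        raise SeparationError("diverging coefficients indicate quasi-separation")

    names = ["const"] + list(predictors)
    ci = res.conf_int(alpha=0.05)
    table = pd.DataFrame(
        {
            "coef": res.params,
            "odds_ratio": np.exp(res.params),
            "ci_low": np.exp(ci[:, 0]),
            "ci_high": np.exp(ci[:, 1]),
            "p_value": res.pvalues,
        },
        index=pd.Index(names, name="predictor"),
    ).drop(index="const")
    return LogisticFit(
        table=table,
        converged=bool(res.mle_retvals.get("converged", False)),
        n_obs=int(res.nobs),
        log_likelihood=float(res.llf),
    )


def baseline_table(covariates: pd.DataFrame) -> pd.DataFrame:
    """Group comparisons between the GC-sensitive and GC-resistant relapse
    groups: chi-square for sex and immunotherapy, Mann-Whitney for the rest."""
    sens = covariates[covariates["group"] == "sensitive"]
    res = covariates[covariates["group"] == "resistant"]
    rows = []

    def _counts(frame, col, levels):
        return [int((frame[col] == lv).sum()) for lv in levels]

    sex_tab = [_counts(sens, "sex", ["female", "male"]),
               _counts(res, "sex", ["female", "male"])]
    stat, _, p = chi_square_test(sex_tab)
    rows.append({"variable": "sex_female", "test": "chi2", "p_value": p})
    immu_levels = list(IMMUNOTHERAPY_CODES)
    immu_tab = np.array([_counts(sens, "immunotherapy", immu_levels),
                         _counts(res, "immunotherapy", immu_levels)])
    immu_tab = immu_tab[:, immu_tab.sum(axis=0) > 0]  # drop empty categories
    if min(immu_tab.shape) >= 2:
        stat, _, p = chi_square_test(immu_tab)
        rows.append({"variable": "immunotherapy", "test": "chi2", "p_value": p})
    for col in ("age", "disease_duration", "edss_prior", "edss_post", "gc_dose_mg"):
        _, p = mann_whitney_u(sens[col], res[col])
        rows.append({"variable": col, "test": "mann_whitney", "p_value": p})
    return pd.DataFrame(rows)
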