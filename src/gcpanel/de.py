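"""Differential expression contrast, BH correction, and the AUC prefilter.

The two-group contrast is a per-gene Welch t-test on log-scale expression
with Benjamini-Hochberg adjustment across all tested genes; a gene passes
the volcano filter when |logFC| exceeds the fold-change threshold AND the
adjusted p-value is below alpha (strict inequalities). The AUC prefilter
reproduces the panel-construction rule: keep genes whose transcriptomic AUC
is > 0.86 or < 0.14 (strict), then drop non-protein-coding genes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

AUC_UPPER = 0.86
AUC_LOWER = 0.14


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def de_contrast(expr_log: pd.DataFrame, groups, lfc_threshold: float = 0.5,
                alpha: float = 0.05, var_floor: float = 1e-12) -> pd.DataFrame:
    """Per-gene Welch t-test between two groups on log-scale expression.

    Returns a frame (gene, log_fc, p_value, adj_p_value, passed) where
    ``log_fc`` is the group-mean difference (second group minus first, in
    the log base of the input) and ``passed`` applies the volcano rule.
    Genes with zero within-group variance get the variance floor and are
    counted in a warning.
    """
    groups = pd.Series(np.asarray(groups), index=expr_log.index)
    names = pd.unique(groups)
    if len(names) != 2:
        raise ValueError("exactly two groups required")
    a = expr_log.loc[groups == names[0]].to_numpy(dtype=float)
    b = expr_log.loc[groups == names[1]].to_numpy(dtype=float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs n >= 2")

    va, vb = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    n_floor = int(((va <= var_floor) | (vb <= var_floor)).sum())
    if n_floor:
        logger.warning("%d gene(s) at the variance floor", n_floor)
    va = np.maximum(va, var_floor)
    vb = np.maximum(vb, var_floor)
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    se2 = va / a.shape[0] + vb / b.shape[0]
    tstat = (mb - ma) / np.sqrt(se2)
    df = se2**2 / (
        (va / a.shape[0]) ** 2 / (a.shape[0] - 1)
        + (vb / b.shape[0]) ** 2 / (b.shape[0] - 1)
    )
    p = 2.0 * sps.t.sf(np.abs(tstat), df)
    adj = bh_adjust(p)
    log_fc = mb - ma
    return pd.DataFrame(
        {
            "gene": list(expr_log.columns),
            "log_fc": log_fc,
            "p_value": p,
            "adj_p_value": adj,
            "passed": (np.abs(log_fc) > lfc_threshold) & (adj < alpha),
        }
    )


def prefilter_by_auc(aucs: pd.Series, annotations: pd.DataFrame,
                     upper: float = AUC_UPPER, lower: float = AUC_LOWER):
    """Panel-candidate selection: AUC > upper or AUC < lower (strict), then
    drop non-protein-coding genes.

    ``annotations`` has columns (gene_id, biotype). Returns
    (candidate gene list, step-count dict). Unannotated survivors are an error.
    """
    aucs = pd.Series(aucs, dtype=float)
    if ((aucs < 0) | (aucs > 1)).any():
        raise ValueError("AUCs must lie in [0, 1]")
    extreme = aucs[(aucs > upper) | (aucs < lower)]
    ann = annotations.set_index("gene_id")["biotype"]
    missing = [g for g in extreme.index if g not in ann.index]
    if missing:
        raise ValueError(f"unannotated genes among AUC survivors: {missing}")
    coding = [g for g in extreme.index if ann[g] == "protein_coding"]
    counts = {
        "n_input": int(aucs.size),
        "n_auc_pass": int(extreme.size),
        "n_non_coding_dropped": int(extreme.size - len(coding)),
        "n_retained": len(coding),
    }
    return coding, counts
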