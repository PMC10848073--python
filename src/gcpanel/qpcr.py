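"""qPCR Ct handling: replicate aggregation and relative-expression normalization.

Relative expression is the ratio Ct_gene / Ct_ACTB against the beta-actin
housekeeping gene. Because a LOWER Ct means HIGHER transcript abundance, the
ratio is an inverse-abundance scale; every cutoff in this package operates on
the ratio scale as measured, never on inferred abundance.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REFERENCE_GENE = "ACTB"
CT_COLUMNS = ["patient_id", "gene_id", "replicate", "ct"]


def read_ct_table(path) -> pd.DataFrame:
    """Read a long-format Ct CSV (patient_id, gene_id, replicate, ct)."""
    records = pd.read_csv(path)
    return validate_ct_records(records)


def validate_ct_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    records = records.loc[:, CT_COLUMNS].copy()
    if records.empty:
        raise ValueError("Ct table is empty")
    if not (records["ct"] > 0).all():
        raise ValueError("Ct values must be strictly positive")
    if records.duplicated(["patient_id", "gene_id", "replicate"]).any():
        raise ValueError("duplicate (patient, gene, replicate) entries")
    return records


def aggregate_replicates(records: pd.DataFrame, method: str = "mean") -> pd.DataFrame:
    """Collapse technical replicates to one Ct per (patient, gene).

    Parameters
    ----------
    records : long-format Ct table (patient_id, gene_id, replicate, ct).
    method : "mean" (default) or "median".

    Returns a long table with one ``ct`` per (patient_id, gene_id).
    """
    if method not in ("mean", "median"):
        raise ValueError(f"unknown aggregation method {method!r}")
    records = validate_ct_records(records)
    n_missing = int(records["ct"].isna().sum())
    if n_missing:
        logger.warning("dropping %d missing Ct replicates", n_missing)
        records = records.dropna(subset=["ct"])
    agg = (
        records.groupby(["patient_id", "gene_id"], sort=False)["ct"]
        .agg(method)
        .reset_index()
    )
    return agg


def normalize_ct(ct_gene, ct_actb):
    """Relative expression as the ratio Ct_gene / Ct_ACTB (both > 0)."""
    ct_gene = np.asarray(ct_gene, dtype=float)
    ct_actb = np.asarray(ct_actb, dtype=float)
    if np.any(~(ct_actb > 0)):
        raise ValueError("ACTB Ct must be strictly positive and present")
    if np.any(~(ct_gene > 0)):
        raise ValueError("target Ct must be strictly positive")
    out = ct_gene / ct_actb
    return float(out) if out.ndim == 0 else out


def expression_matrix(aggregated: pd.DataFrame) -> pd.DataFrame:
    """Build a patients x genes relative-expression matrix.

    ACTB is consumed by the normalization and never appears as a column.
    A patient with no ACTB measurement raises a normalization error.
    """
    wide = aggregated.pivot(index="patient_id", columns="gene_id", values="ct")
    if REFERENCE_GENE not in wide.columns:
        raise ValueError(f"reference gene {REFERENCE_GENE} absent from Ct table")
    actb = wide.pop(REFERENCE_GENE)
    bad = actb.index[~(actb > 0) | actb.isna()]
    if len(bad):
        raise ValueError(f"missing or invalid ACTB Ct for patients: {list(bad)}")
    expr = wide.div(actb, axis=0)
    expr.columns.name = None
    expr.index.name = "patient_id"
    return expr


def read_expression_matrix(path) -> pd.DataFrame:
    """Read a wide CSV of already-normalized relative expression."""
    expr = pd.read_csv(path, index_col=0)
    expr.index.name = "patient_id"
    if REFERENCE_GENE in expr.columns:
        raise ValueError("normalized matrix must not contain ACTB")
    if (expr.to_numpy(dtype=float) <= 0).any():
        raise ValueError("relative expression must be strictly positive")
    return expr


def write_expression_matrix(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, float_format="%.12g")
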