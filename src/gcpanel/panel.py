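"""Reference 12-gene qPCR panel: cutoffs, operating points, directions.

The panel ships as a packaged CSV holding, per gene, the ROC-derived
relative-expression cutoff (Ct_gene/Ct_ACTB ratio scale), the sensitivity
and 1-specificity achieved at that cutoff in the discovery qPCR cohort
(10 GC-sensitive vs 15 GC-resistant relapsing MS patients), and the AUC.
A gene is "up" in GC-resistant relapse iff its AUC exceeds 0.5 under the
higher-ratio-positive orientation; up-genes score 1 at ratios >= cutoff,
down-genes score 1 at ratios strictly below it.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

PANEL_COLUMNS = ["gene", "cutoff", "sensitivity", "one_minus_specificity", "auc"]
N_PANEL_GENES = 12


def load_reference_panel() -> pd.DataFrame:
    """Load the packaged 12-gene panel with a derived ``direction`` column."""
    with resources.files("gcpanel.data").joinpath("qpcr_panel.csv").open() as fh:
        panel = pd.read_csv(fh)
    return validate_panel(panel)


def read_panel(path) -> pd.DataFrame:
    """Read a panel CSV (same columns as the packaged fixture) and validate it."""
    return validate_panel(pd.read_csv(path))


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Check panel invariants and attach the scoring direction.

    Direction is ``up`` iff auc > 0.5 (ties break to up): for up-genes the
    positivity rule is ratio >= cutoff, for down-genes ratio < cutoff.
    """
    missing = [c for c in PANEL_COLUMNS if c not in panel.columns]
    if missing:
        raise ValueError(f"panel is missing columns: {missing}")
    panel = panel.loc[:, PANEL_COLUMNS].copy()
    if panel["gene"].duplicated().any():
        raise ValueError("duplicate gene ids in panel")
    if not (panel["cutoff"] > 0).all():
        raise ValueError("panel cutoffs must be strictly positive")
    for col in ("sensitivity", "one_minus_specificity", "auc"):
        if not panel[col].between(0.0, 1.0).all():
            raise ValueError(f"panel column {col!r} must lie in [0, 1]")
    panel["direction"] = ["up" if a >= 0.5 else "down" for a in panel["auc"]]
    return panel.reset_index(drop=True)
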