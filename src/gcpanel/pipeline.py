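"""End-to-end reproducible run: simulate (or load) -> score -> classify ->
baseline stats -> adjusted logistic models -> report.

The run report (JSON + Markdown) embeds the seed, a config hash, the package
version, per-gene operating points at the panel cutoffs, the score
distribution per class, the score-classifier summary, the baseline
comparisons, and both adjusted logistic fits (with and without recruitment
center)."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .panel import load_reference_panel, read_panel
from .qpcr import read_expression_matrix, write_expression_matrix
from .scoring import CompositeScoreClassifier, binarize, composite_score
from .simulate import GeneratorConfig, generate_cohort
from .stats import SeparationError, baseline_table, encode_design, fit_logistic

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    input_mode: str = "synthetic"  # or "csv"
    expression_path: str | None = None
    covariates_path: str | None = None
    panel_path: str | None = None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    min_specificity: float = 0.80
    legacy_score_cutoff: float | None = None
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self):
        if not (0.0 < self.min_specificity < 1.0):
            raise ValueError("min_specificity must lie in (0, 1)")
        if self.input_mode not in ("synthetic", "csv"):
            raise ValueError(f"unknown input mode {self.input_mode!r}")
        if self.input_mode == "csv" and not (
            self.expression_path and self.covariates_path
        ):
            raise ValueError("csv mode requires expression and covariate paths")


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _per_gene_operating_points(expr, labels, panel) -> pd.DataFrame:
    bits, _ = binarize(expr, panel)
    lab = labels.loc[bits.index]
    res, sens = bits[lab == "resistant"], bits[lab == "sensitive"]
    return pd.DataFrame(
        {
            "gene": bits.columns,
            "cutoff": panel.set_index("gene").loc[bits.columns, "cutoff"].to_numpy(),
            "sensitivity": res.mean().to_numpy(),
            "specificity": 1.0 - sens.mean().to_numpy(),
        }
    )


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline and return the run report as a dict."""
    panel = (
        read_panel(config.panel_path) if config.panel_path else load_reference_panel()
    )

    if config.input_mode == "synthetic":
        gen = GeneratorConfig(
            **{**asdict(config.generator), "seed": config.seed}
        )
        covariates, expr, labels = generate_cohort(gen, panel=panel)
    else:
        expr = read_expression_matrix(config.expression_path)
        covariates = pd.read_csv(config.covariates_path)
        labels = pd.Series(
            covariates["group"].to_numpy(),
            index=covariates["patient_id"],
            name="group",
        )
    logger.info(
        "cohort: %d patients (%d resistant), %d panel genes",
        len(labels), int((labels == "resistant").sum()), len(panel),
    )

    clf = CompositeScoreClassifier(
        panel=panel,
        min_specificity=config.min_specificity,
        legacy_cutoff=config.legacy_score_cutoff,
        positive_label="resistant",
    ).fit(expr, labels.loc[expr.index])
    bits = clf.binarizer_.transform(expr)
    excluded = clf.binarizer_.excluded_
    scores = composite_score(bits)
    logger.info("scored %d patients; excluded %d", len(scores), len(excluded))

    score_dist = {
        grp: scores[labels.loc[scores.index] == grp]
        .value_counts()
        .sort_index()
        .to_dict()
        for grp in ("sensitive", "resistant")
    }

    baseline = baseline_table(covariates)
    design = encode_design(covariates, scores)
    design_center = encode_design(covariates, scores, include_center=True)
    fits = {}
    for name, d in (("adjusted", design), ("adjusted_center", design_center)):
        try:
            fit = fit_logistic(d)
            fits[name] = {
                "table": fit.table.reset_index().to_dict(orient="records"),
                "converged": fit.converged,
                "n_obs": fit.n_obs,
                "log_likelihood": fit.log_likelihood,
            }
        except (SeparationError, ValueError) as exc:
            fits[name] = {"error": str(exc)}

    report = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "design_flags": {
            "rate_interpretation": config.generator.rate_interpretation,
            "min_specificity": config.min_specificity,
            "legacy_score_cutoff": config.legacy_score_cutoff,
            "complete_case_scoring": True,
            "up_gene_rule": ">=cutoff",
            "down_gene_rule": "<cutoff",
        },
        "cohort": {
            "n_total": int(len(labels)),
            "n_sensitive": int((labels == "sensitive").sum()),
            "n_resistant": int((labels == "resistant").sum()),
            "n_excluded_incomplete_panel": len(excluded),
            "excluded_patients": [str(p) for p in excluded],
        },
        "per_gene_operating_points": _per_gene_operating_points(
            expr, labels, panel
        ).to_dict(orient="records"),
        "score_distribution": {
            grp: {int(k): int(v) for k, v in dist.items()}
            for grp, dist in score_dist.items()
        },
        "score_classifier": {
            "score_cutoff": clf.score_cutoff_,
            "sensitivity": clf.sensitivity_,
            "specificity": clf.specificity_,
            "auc": clf.auc_,
        },
        "baseline_statistics": baseline.to_dict(orient="records"),
        "logistic_fits": fits,
    }

    if config.output_dir:
        _write_outputs(config, report, covariates, expr, bits, scores)
    return report


def _write_outputs(config, report, covariates, expr, bits, scores):
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    covariates.to_csv(out / "covariates.csv", index=False)
    write_expression_matrix(expr, out / "expression.csv")
    bits.assign(score=scores).to_csv(out / "scores.csv")
    (out / "report.json").write_text(json.dumps(report, indent=2))
    (out / "report.md").write_text(_markdown_report(report))


def _markdown_report(report: dict) -> str:
    sc = report["score_classifier"]
    lines = [
        "# GC-resistance panel run report",
        "",
        f"- package version: {report['package_version']}",
        f"- seed: {report['seed']}  config hash: {report['config_hash']}",
        f"- cohort: {report['cohort']['n_total']} patients "
        f"({report['cohort']['n_resistant']} GC-resistant, "
        f"{report['cohort']['n_sensitive']} GC-sensitive); "
        f"{report['cohort']['n_excluded_incomplete_panel']} excluded (incomplete panel)",
        "",
        "## Score classifier",
        f"- cutoff: score >= {sc['score_cutoff']:g}",
        f"- sensitivity {sc['sensitivity']:.3f}, specificity {sc['specificity']:.3f}, "
        f"AUC {sc['auc']:.3f}",
        "",
        "## Per-gene operating points",
        "",
        "| gene | cutoff | sensitivity | specificity |",
        "|---|---|---|---|",
    ]
    for row in report["per_gene_operating_points"]:
        lines.append(
            f"| {row['gene']} | {row['cutoff']:.6f} | "
            f"{row['sensitivity']:.3f} | {row['specificity']:.3f} |"
        )
    lines += ["", "## Adjusted logistic models", ""]
    for name, fit in report["logistic_fits"].items():
        lines.append(f"### {name}")
        if "error" in fit:
            lines.append(f"- not estimable: {fit['error']}")
            lines.append("")
            continue
        lines.append("")
        lines.append("| predictor | OR | 95% CI | p |")
        lines.append("|---|---|---|---|")
        for row in fit["table"]:
            lines.append(
                f"| {row['predictor']} | {row['odds_ratio']:.2f} | "
                f"{row['ci_low']:.2f}-{row['ci_high']:.2f} | {row['p_value']:.2f} |"
            )
        lines.append("")
    return "\n".join(lines) + "\n"
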