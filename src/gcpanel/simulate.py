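"""Synthetic relapse cohorts calibrated to the panel's printed operating points.

No patient-level data is deposited for this panel, so downstream stages are
exercised on synthetic cohorts built to match the panel's published per-gene
operating points exactly (in expectation).

Gene model
----------
Each gene j has a standard-normal latent liability per patient i,

    Z_ij = delta_j * 1[group = resistant] + lambda * L_i + sqrt(1-lambda^2) * eps_ij,

with L_i a shared patient factor and eps_ij idiosyncratic noise (both
standard normal, independent). The marginal variance is 1 in both groups for
any loading lambda, so with

    t_j     = -Phi^{-1}(rate_sensitive_j)
    delta_j =  Phi^{-1}(rate_resistant_j) - Phi^{-1}(rate_sensitive_j)

the indicator P(Z_ij >= t_j) equals the target positivity rate in each group
exactly, for any lambda. An affine map then places the indicator boundary at
the published cutoff on the relative-expression (Ct ratio) scale:
up-genes map z -> cutoff + scale*(z - t), down-genes z -> cutoff - scale*(z - t),
so the published >= / < scoring rules recover the latent indicator.

Target rates come from the panel's printed sensitivity / 1-specificity
columns. Under the default ``complement`` interpretation those columns are
read in a fixed higher-ratio-positive orientation, so for down-genes (whose
indicator fires below the cutoff) the rates are complemented; ``as_printed``
uses them unchanged for every gene. Covariates are drawn to match the
published baseline table marginals; no covariate-expression dependence is
induced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, truncnorm

from .panel import load_reference_panel, validate_panel

logger = logging.getLogger(__name__)

RATE_INTERPRETATIONS = ("complement", "as_printed")


@dataclass(frozen=True)
class GeneratorConfig:
    """Cohort sizes, shared latent loading, seed, and rate interpretation.

    Defaults are the pooled two-center relapse cohort: 31 GC-sensitive
    (10 Bern + 21 Athens) and 16 GC-resistant (15 Bern + 1 Athens).
    """

    n_sensitive: int = 31
    n_resistant: int = 16
    loading: float = 0.3
    seed: int = 0
    rate_interpretation: str = "complement"
    scale: float = 0.1  # ratio-scale units per latent SD

    def __post_init__(self):
        if self.n_sensitive < 1 or self.n_resistant < 1:
            raise ValueError("group sizes must be >= 1")
        if not (0.0 <= self.loading < 1.0):
            raise ValueError("loading must lie in [0, 1)")
        if self.rate_interpretation not in RATE_INTERPRETATIONS:
            raise ValueError(
                f"unknown rate_interpretation {self.rate_interpretation!r}"
            )


@dataclass(frozen=True)
class GroupCovariates:
    """Marginal covariate targets for one clinical group."""

    age_mean: float
    age_min: float
    age_max: float
    female_fraction: float
    duration_mean: float
    duration_min: float
    duration_max: float
    edss_prior_median: float
    edss_prior_min: float
    edss_prior_max: float
    edss_post_median: float
    edss_post_min: float
    edss_post_max: float
    dose_mean: float
    dose_min: float
    dose_max: float
    immunotherapy_probs: tuple  # (none, mild-to-moderate, high)
    center_bern_fraction: float

    def __post_init__(self):
        if not np.isclose(sum(self.immunotherapy_probs), 1.0):
            raise ValueError("immunotherapy probabilities must sum to 1")


# Published baseline marginals of the pooled relapse groups. Immunotherapy
# counts: sensitive (18, 10, 6)/34, resistant (12, 4, 0)/16. Centers:
# sensitive 10/31 Bern, resistant 15/16 Bern.
DEFAULT_COVARIATES = {
    "sensitive": GroupCovariates(
        age_mean=35.3, age_min=18, age_max=64,
        female_fraction=25 / 34,
        duration_mean=4.1, duration_min=0, duration_max=19,
        edss_prior_median=2.5, edss_prior_min=1.0, edss_prior_max=6.0,
        edss_post_median=1.5, edss_post_min=0.0, edss_post_max=5.0,
        dose_mean=4956, dose_min=1500, dose_max=13000,
        immunotherapy_probs=(18 / 34, 10 / 34, 6 / 34),
        center_bern_fraction=10 / 31,
    ),
    "resistant": GroupCovariates(
        age_mean=34.8, age_min=23, age_max=57,
        female_fraction=12 / 16,
        duration_mean=1.6, duration_min=0, duration_max=13,
        edss_prior_median=2.89, edss_prior_min=1.5, edss_prior_max=5.0,
        edss_post_median=3.25, edss_post_min=1.5, edss_post_max=5.0,
        dose_mean=5794, dose_min=1200, dose_max=11000,
        immunotherapy_probs=(12 / 16, 4 / 16, 0.0),
        center_bern_fraction=15 / 16,
    ),
}

IMMUNOTHERAPY_LEVELS = ("none", "mild_to_moderate", "high")


def derive_positivity_rates(panel: pd.DataFrame,
                            interpretation: str = "complement") -> pd.DataFrame:
    """Per-gene indicator firing rates (resistant, sensitive) from the panel.

    Up-genes fire at ratio >= cutoff, so their rates are the printed
    (sensitivity, 1-specificity) under both interpretations. Down-genes fire
    at ratio < cutoff; under ``complement`` the printed columns are read in
    the higher-positive orientation and complemented, under ``as_printed``
    they are used unchanged.
    """
    if interpretation not in RATE_INTERPRETATIONS:
        raise ValueError(f"unknown interpretation {interpretation!r}")
    panel = validate_panel(panel.drop(columns="direction", errors="ignore"))
    down = panel["direction"] == "down"
    rr = panel["sensitivity"].to_numpy(dtype=float).copy()
    rs = panel["one_minus_specificity"].to_numpy(dtype=float).copy()
    if interpretation == "complement":
        rr[down] = 1.0 - rr[down]
        rs[down] = 1.0 - rs[down]
    return pd.DataFrame(
        {"gene": panel["gene"], "rate_resistant": rr, "rate_sensitive": rs}
    )


def calibrate_gene_model(panel: pd.DataFrame, rates: pd.DataFrame,
                         loading: float = 0.3, scale: float = 0.1) -> pd.DataFrame:
    """Latent-model parameters (shift, latent threshold, scale) per gene.

    Closed-form probit calibration: latent_threshold = -Phi^{-1}(rate_sens),
    shift = Phi^{-1}(rate_res) - Phi^{-1}(rate_sens). Valid for any loading
    because the marginal latent variance is 1. Degenerate rates (exactly 0
    or 1) become point masses at +/-inf thresholds with a warning.
    """
    panel = validate_panel(panel.drop(columns="direction", errors="ignore"))
    merged = panel.merge(rates, on="gene", validate="one_to_one")
    rr = merged["rate_resistant"].to_numpy(dtype=float)
    rs = merged["rate_sensitive"].to_numpy(dtype=float)
    degenerate = (rr <= 0) | (rr >= 1) | (rs <= 0) | (rs >= 1)
    if degenerate.any():
        logger.warning(
            "degenerate firing rates for %s; using point-mass thresholds",
            list(merged.loc[degenerate, "gene"]),
        )
    with np.errstate(divide="ignore"):
        t = -norm.ppf(rs)
        delta = norm.ppf(rr) - norm.ppf(rs)
    delta = np.where(np.isfinite(delta), delta, 0.0)
    return pd.DataFrame(
        {
            "gene": merged["gene"],
            "direction": merged["direction"],
            "cutoff": merged["cutoff"],
            "shift": delta,
            "latent_threshold": t,
            "scale": scale,
            "rate_resistant": rr,
            "rate_sensitive": rs,
        }
    )


def _truncated_normal(rng, mean, lo, hi, size):
    sd = max((hi - lo) / 4.0, 1e-9)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _edss_grid(rng, median, lo, hi, size):
    # 0.5-step ordinal grid spanning [lo, hi], centred on the printed median
    x = _truncated_normal(rng, median, lo, hi, size)
    return np.clip(np.round(x * 2.0) / 2.0, lo, hi)


def _sample_group_covariates(rng, group: str, spec: GroupCovariates,
                             n: int, start_id: int) -> pd.DataFrame:
    n_bern = int(round(n * spec.center_bern_fraction))
    center = np.array(["bern"] * n_bern + ["athens"] * (n - n_bern))
    immu = rng.choice(IMMUNOTHERAPY_LEVELS, size=n, p=spec.immunotherapy_probs)
    return pd.DataFrame(
        {
            "patient_id": [f"P{start_id + k:03d}" for k in range(n)],
            "group": group,
            "age": _truncated_normal(rng, spec.age_mean, spec.age_min, spec.age_max, n),
            "sex": np.where(rng.random(n) < spec.female_fraction, "female", "male"),
            "disease_duration": _truncated_normal(
                rng, spec.duration_mean, spec.duration_min, spec.duration_max, n
            ),
            "edss_prior": _edss_grid(
                rng, spec.edss_prior_median, spec.edss_prior_min, spec.edss_prior_max, n
            ),
            "edss_post": _edss_grid(
                rng, spec.edss_post_median, spec.edss_post_min, spec.edss_post_max, n
            ),
            "gc_dose_mg": _truncated_normal(
                rng, spec.dose_mean, spec.dose_min, spec.dose_max, n
            ),
            "immunotherapy": immu,
            "center": center,
        }
    )


def generate_cohort(config: GeneratorConfig, panel: pd.DataFrame | None = None,
                    covariates: dict | None = None):
    """Draw a synthetic cohort: (covariate table, expression matrix, labels).

    Reproducible given the config seed; expression values are positive Ct
    ratios whose per-gene indicator rates match the calibration targets in
    expectation for both groups.
    """
    if panel is None:
        panel = load_reference_panel()
    if covariates is None:
        covariates = DEFAULT_COVARIATES
    rng = np.random.default_rng(config.seed)

    rates = derive_positivity_rates(panel, config.rate_interpretation)
    model = calibrate_gene_model(panel, rates, config.loading, config.scale)

    cov = pd.concat(
        [
            _sample_group_covariates(
                rng, "sensitive", covariates["sensitive"], config.n_sensitive, 0
            ),
            _sample_group_covariates(
                rng, "resistant", covariates["resistant"], config.n_resistant,
                config.n_sensitive,
            ),
        ],
        ignore_index=True,
    )
    labels = pd.Series(
        cov["group"].to_numpy(), index=cov["patient_id"], name="group"
    )

    n = len(cov)
    resistant = (labels == "resistant").to_numpy()
    lam = config.loading
    shared = rng.standard_normal(n)
    eps = rng.standard_normal((n, len(model)))
    z0 = lam * shared[:, None] + np.sqrt(1.0 - lam**2) * eps

    # per-group latent thresholds; for non-degenerate rates
    # t_res == latent_threshold - shift
    with np.errstate(divide="ignore"):
        t_sens = -norm.ppf(model["rate_sensitive"].to_numpy())
        t_res = -norm.ppf(model["rate_resistant"].to_numpy())
    t = np.where(resistant[:, None], t_res[None, :], t_sens[None, :])

    up = (model["direction"] == "up").to_numpy()
    sign = np.where(up, 1.0, -1.0)
    cutoff = model["cutoff"].to_numpy()
    scale = model["scale"].to_numpy()
    with np.errstate(invalid="ignore"):
        values = cutoff + scale * sign * (z0 - t)
    # degenerate rates (0 or 1): deterministic point mass on the firing side
    # iff the group's rate is 1 (fires: value >= cutoff for up, < cutoff for down)
    rate = np.where(
        resistant[:, None],
        model["rate_resistant"].to_numpy()[None, :],
        model["rate_sensitive"].to_numpy()[None, :],
    )
    degenerate = ~np.isfinite(t)
    fire_mass = cutoff + sign * scale
    quiet_mass = cutoff - sign * scale
    values = np.where(
        degenerate, np.where(rate >= 1.0, fire_mass, quiet_mass), values
    )
    values = np.maximum(values, 1e-9)  # Ct ratios are positive

    expr = pd.DataFrame(values, index=cov["patient_id"], columns=list(model["gene"]))
    expr.index.name = "patient_id"
    return cov, expr, labels
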