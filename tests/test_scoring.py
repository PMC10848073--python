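"""Panel binarization, 0-12 composite scoring, score classifier, and the
Poisson-binomial independence oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from gcpanel import (
    CompositeScoreClassifier,
    PanelBinarizer,
    binarize,
    composite_score,
    derive_positivity_rates,
    pmf_auc,
    poisson_binomial_pmf,
    score_classifier,
)


def enumerate_pmf(ps):
    """Exact score pmf by full enumeration over all 2^n outcomes."""
    pmf = np.zeros(len(ps) + 1)
    for bits in itertools.product((0, 1), repeat=len(ps)):
        prob = 1.0
        for b, p in zip(bits, ps):
            prob *= p if b else 1.0 - p
        pmf[sum(bits)] += prob
    return pmf


def expr_frame(panel, values_by_gene):
    return pd.DataFrame([values_by_gene], index=["p1"])[list(panel["gene"])]


class TestBinarize:
    def test_boundary_conventions(self, panel):
        # up-gene: inclusive >=; down-gene: strict <, so the exact cutoff is 0
        lookup = panel.set_index("gene")
        values = {g: lookup.loc[g, "cutoff"] for g in panel["gene"]}
        bits, excluded = binarize(expr_frame(panel, values), panel)
        assert not excluded
        for _, row in panel.iterrows():
            expected = 1 if row["direction"] == "up" else 0
            assert bits.loc["p1", row["gene"]] == expected

    def test_extreme_values_fire_all(self, panel):
        values = {
            row["gene"]: (1e9 if row["direction"] == "up" else 1e-9)
            for _, row in panel.iterrows()
        }
        bits, _ = binarize(expr_frame(panel, values), panel)
        assert composite_score(bits).iloc[0] == 12

    def test_missing_gene_excludes_patient(self, panel, small_cohort):
        _, expr, _ = small_cohort
        expr = expr.copy()
        expr.iloc[0, 0] = np.nan
        bits, excluded = binarize(expr, panel)
        assert excluded == [expr.index[0]]
        assert len(bits) == len(expr) - 1

    def test_absent_panel_column_is_an_error(self, panel, small_cohort):
        _, expr, _ = small_cohort
        with pytest.raises(ValueError, match="AIM2"):
            binarize(expr.drop(columns=["AIM2"]), panel)


class TestCompositeScore:
    @pytest.mark.parametrize(
        "bits, expected",
        [([1] * 12, 12), ([0] * 12, 0), ([1, 0] * 6, 6)],
    )
    def test_sum(self, bits, expected):
        frame = pd.DataFrame([bits], index=["p1"])
        assert composite_score(frame).iloc[0] == expected

    def test_score_mass_conservation(self, panel, small_cohort):
        _, expr, _ = small_cohort
        bits, _ = binarize(expr, panel)
        scores = composite_score(bits)
        assert scores.sum() == bits.to_numpy().sum()
        assert scores.between(0, 12).all()


class TestScoreClassifier:
    def test_perfectly_separated(self):
        scores = [12] * 5 + [0] * 5
        labels = ["resistant"] * 5 + ["sensitive"] * 5
        s = score_classifier(scores, labels, 0.8)
        assert (s.score_cutoff, s.sensitivity, s.specificity, s.auc) == (12, 1, 1, 1)

    def test_legacy_cutoff_ceils_to_next_integer(self):
        scores = [9, 9, 8, 8, 7, 0, 1, 2, 9, 3]
        labels = ["resistant"] * 5 + ["sensitive"] * 5
        s = score_classifier(scores, labels, 0.8, legacy_cutoff=8.8)
        assert s.score_cutoff == 9  # positivity iff score >= 9
        assert s.sensitivity == pytest.approx(2 / 5)
        assert s.specificity == pytest.approx(4 / 5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            score_classifier([1, 2], ["resistant", "resistant"], 0.8)

    def test_empirical_auc_matches_pmf_oracle(self, rng, panel):
        rates = derive_positivity_rates(panel)
        pr = poisson_binomial_pmf(rates["rate_resistant"])
        ps = poisson_binomial_pmf(rates["rate_sensitive"])
        expected_auc = pmf_auc(pr, ps)
        n = 4000
        draws_r = (rng.random((n, 12)) < rates["rate_resistant"].to_numpy()).sum(1)
        draws_s = (rng.random((n, 12)) < rates["rate_sensitive"].to_numpy()).sum(1)
        s = score_classifier(
            np.r_[draws_r, draws_s],
            np.r_[["resistant"] * n, ["sensitive"] * n],
            0.8,
        )
        # 3 sigma of the empirical AUC via the pairwise-comparison variance bound
        se = np.sqrt(expected_auc * (1 - expected_auc) / n)
        assert abs(s.auc - expected_auc) < 3 * se


class TestPoissonBinomial:
    def test_degenerate_point_masses(self):
        assert poisson_binomial_pmf([0.0] * 12)[0] == 1.0
        assert poisson_binomial_pmf([1.0] * 12)[12] == 1.0

    def test_pmf_normalizes(self, panel):
        rates = derive_positivity_rates(panel)
        pmf = poisson_binomial_pmf(rates["rate_resistant"])
        assert pmf.size == 13
        assert pmf.sum() == pytest.approx(1.0, abs=1e-12)

    def test_dp_equals_full_enumeration(self, panel):
        rates = derive_positivity_rates(panel)
        for col in ("rate_resistant", "rate_sensitive"):
            np.testing.assert_allclose(
                poisson_binomial_pmf(rates[col]),
                enumerate_pmf(rates[col].to_numpy()),
                atol=1e-12,
            )

    def test_dp_tail_matches_monte_carlo(self, rng, panel):
        rates = derive_positivity_rates(panel)["rate_resistant"].to_numpy()
        tail = poisson_binomial_pmf(rates)[9:].sum()  # P(S >= 9)
        n = 100_000
        draws = (rng.random((n, 12)) < rates).sum(axis=1)
        emp = np.mean(draws >= 9)
        se = np.sqrt(tail * (1 - tail) / n)
        assert abs(emp - tail) < 3 * se

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            poisson_binomial_pmf([0.5, 1.2])

    def test_augmentation_identity(self, rng):
        # exact change in tie-corrected AUC from adding one gene with rates
        # (hi, lo): dAUC = 0.5*hi*(1-lo)*[P(=) + P(r = s-1)]
        #                - 0.5*lo*(1-hi)*[P(=) + P(r = s+1)]
        for _ in range(20):
            k = int(rng.integers(3, 10))
            pr, ps = rng.random(k), rng.random(k)
            fr, fs = poisson_binomial_pmf(pr), poisson_binomial_pmf(ps)
            base = pmf_auc(fr, fs)
            p_eq = float(np.sum(fr * fs))
            p_minus1 = float(np.sum(fr[:-1] * fs[1:]))  # P(S_r = S_s - 1)
            p_plus1 = float(np.sum(fr[1:] * fs[:-1]))   # P(S_r = S_s + 1)
            lo, hi = np.sort(rng.random(2))
            aug = pmf_auc(
                poisson_binomial_pmf(np.r_[pr, hi]),
                poisson_binomial_pmf(np.r_[ps, lo]),
            )
            delta = 0.5 * hi * (1 - lo) * (p_eq + p_minus1) - 0.5 * lo * (
                1 - hi
            ) * (p_eq + p_plus1)
            assert aug - base == pytest.approx(delta, abs=1e-12)

    def test_strong_gene_augmentation_raises_panel_auc(self, panel):
        # a clearly informative marker added to the reference rates helps
        rates = derive_positivity_rates(panel)
        base = pmf_auc(
            poisson_binomial_pmf(rates["rate_resistant"]),
            poisson_binomial_pmf(rates["rate_sensitive"]),
        )
        aug = pmf_auc(
            poisson_binomial_pmf(np.r_[rates["rate_resistant"], 0.85]),
            poisson_binomial_pmf(np.r_[rates["rate_sensitive"], 0.15]),
        )
        assert aug > base


class TestEstimators:
    def test_fixed_panel_classifier_reports_operating_point(self, panel, small_cohort):
        _, expr, labels = small_cohort
        clf = CompositeScoreClassifier(panel=panel).fit(expr, labels)
        assert 0 <= clf.score_cutoff_ <= 12
        assert clf.specificity_ >= 0.8
        preds = clf.predict(expr)
        scores = clf.decision_function(expr)
        assert ((preds == "resistant") == (scores >= clf.score_cutoff_)).all()

    def test_learned_panel_respects_specificity_floor(self, panel, small_cohort):
        _, expr, labels = small_cohort
        bin_ = PanelBinarizer(min_specificity=0.8).fit(expr, labels)
        assert (bin_.panel_["one_minus_specificity"] <= 0.2 + 1e-12).all()
        bits = bin_.transform(expr)
        assert set(np.unique(bits)) <= {0, 1}

    @pytest.mark.parametrize("interpretation", ["complement", "as_printed"])
    def test_learned_directions_match_analytic_value_shift(self, panel, interpretation):
        # the generator shifts each gene's values by sign * scale * delta
        # (delta the probit shift); per-gene ROC direction inference must
        # recover the sign of that shift whenever it is decisive
        from scipy.stats import norm

        from gcpanel import GeneratorConfig, generate_cohort

        config = GeneratorConfig(
            n_sensitive=2000, n_resistant=2000, loading=0.0, seed=11,
            rate_interpretation=interpretation,
        )
        _, expr, labels = generate_cohort(config, panel=panel)
        bin_ = PanelBinarizer(min_specificity=0.8).fit(expr, labels)
        learned = bin_.panel_.set_index("gene")["direction"]
        rates = derive_positivity_rates(panel, interpretation).set_index("gene")
        for _, row in panel.iterrows():
            gene = row["gene"]
            delta = norm.ppf(rates.loc[gene, "rate_resistant"]) - norm.ppf(
                rates.loc[gene, "rate_sensitive"]
            )
            value_shift = delta if row["direction"] == "up" else -delta
            if abs(delta) < 0.1:
                continue  # shift too small to call at this n
            assert learned[gene] == ("up" if value_shift > 0 else "down"), gene

    def test_sklearn_params_roundtrip(self, panel):
        clf = CompositeScoreClassifier(panel=panel, min_specificity=0.75)
        params = clf.get_params()
        assert params["min_specificity"] == 0.75
        clf.set_params(min_specificity=0.9)
        assert clf.min_specificity == 0.9
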