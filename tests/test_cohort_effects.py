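"""Efficacy changes, demographic correlations, group tests, co-treatments."""

import numpy as np
import pytest
from scipy import stats

from virtrial.cohort_effects import (
    CotreatmentResult,
    EffectsError,
    categorize_correlation,
    cotreatment_impact,
    covariate_isolation,
    demographic_correlation,
    demographic_correlation_table,
    efficacy_change,
    group_comparison,
    significance_band,
)
from virtrial.definitions import DrugDefinition, ProteinRef, Target


def pool_of(n):
    return [
        DrugDefinition(f"pool{i}", [Target(ProteinRef("A"), 1)]) for i in range(n)
    ]


class TestEfficacyChange:
    def test_reference_group_scores_100(self):
        treated = [0.3, 0.4, 0.5]
        baseline = [0.0, 0.1, 0.2]
        delta, pct = efficacy_change(treated, baseline, 0.3)
        assert delta == pytest.approx(0.3)
        assert pct == pytest.approx(100.0)

    def test_half_reference_scores_50(self):
        _, pct = efficacy_change([0.15, 0.15], [0.0, 0.0], 0.3)
        assert pct == pytest.approx(50.0)

    def test_hand_computed_three_patients(self):
        delta, pct = efficacy_change([0.2, 0.5, 0.8], [0.1, 0.2, 0.3], 0.6)
        assert delta == pytest.approx(0.3)
        assert pct == pytest.approx(50.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(EffectsError):
            efficacy_change([0.1], [0.0], 0.0)


class TestCorrelationCategories:
    @pytest.mark.parametrize(
        "rho,expected",
        [
            (0.85, "Strong"), (0.8, "Strong"), (0.79, "Moderate"),
            (0.5, "Moderate"), (0.49, "Low"), (0.3, "Low"),
            (0.29, "Negligible"), (0.0, "Negligible"),
            (-0.85, "Strong"), (-0.31, "Low"),
        ],
    )
    def test_bands_partition_with_inclusive_boundaries(self, rho, expected):
        assert categorize_correlation(rho, fdr=0.01) == expected

    def test_not_significant_overrides_band(self):
        assert categorize_correlation(0.9, fdr=0.2) == "NotSignificant"

    def test_perfect_negative_correlation(self):
        x = np.arange(10.0)
        res = demographic_correlation(x, -2 * x + 3)
        assert res.rho == pytest.approx(-1.0)
        assert res.category == "Strong"

    def test_zero_variance_rejected(self):
        with pytest.raises(EffectsError):
            demographic_correlation([1.0] * 5, [0.1, 0.2, 0.3, 0.4, 0.5])

    def test_table_applies_bh_family(self):
        import pandas as pd

        rng = np.random.default_rng(1)
        n = 60
        age = rng.uniform(20, 60, n)
        noise = rng.normal(0, 1, n)
        df = pd.DataFrame(
            {"age": age, "noise": noise, "ts": -0.05 * age + rng.normal(0, 0.2, n)}
        )
        res = demographic_correlation_table(df, "ts", ["age", "noise"])
        assert res["age"].category in ("Strong", "Moderate")
        assert res["age"].fdr <= 0.05
        assert res["noise"].fdr >= res["noise"].p  # BH never lowers a raw p


class TestCovariateIsolation:
    def test_recovers_true_dependency(self):
        """tSignal built purely from age: the age correlation survives inside
        every BMI stratum, the BMI correlation does not."""
        rng = np.random.default_rng(7)
        n = 600
        age = rng.uniform(6, 17, n)
        bmi = rng.uniform(14, 25, n)  # independent of age by construction
        ts = -0.04 * age + rng.normal(0, 0.02, n)
        res = covariate_isolation(age, bmi, ts, strata=3)
        assert all(r.rho < -0.8 for r in res.per_stratum["age"])
        assert abs(res.pooled["bmi"]) < 0.2
        assert res.pooled["age"] < -0.8

    def test_null_has_no_significant_strata(self):
        rng = np.random.default_rng(8)
        n = 500
        age = rng.uniform(18, 65, n)
        bmi = rng.uniform(18, 35, n)
        ts = rng.normal(0, 1, n)
        res = covariate_isolation(age, bmi, ts, strata=3)
        for results in res.per_stratum.values():
            for r in results:
                assert r.category in ("NotSignificant", "Negligible")

    def test_single_stratum_reduces_to_plain_correlation(self):
        rng = np.random.default_rng(9)
        age = rng.uniform(20, 60, 50)
        bmi = rng.uniform(18, 30, 50)
        ts = 0.1 * age + rng.normal(0, 1, 50)
        res = covariate_isolation(age, bmi, ts, strata=1)
        plain = stats.pearsonr(age, ts)
        assert len(res.per_stratum["age"]) == 1
        assert res.per_stratum["age"][0].rho == pytest.approx(plain.statistic)


class TestGroupComparison:
    def test_identical_groups_not_significant(self):
        g = [0.1, 0.2, 0.3, 0.15, 0.25]
        res = group_comparison(g, g)
        assert res.band == "ns"
        assert res.p > 0.9

    def test_normality_gate_routes_to_wilcoxon(self):
        """Lognormal samples fail the Jarque-Bera gate and take the
        rank-sum path; normal samples take the t path."""
        rng = np.random.default_rng(10)
        skewed_a = rng.lognormal(0, 1, 200)
        skewed_b = rng.lognormal(0.5, 1, 200)
        assert group_comparison(skewed_a, skewed_b).test_used == "wilcoxon"
        norm_a = rng.normal(0, 1, 200)
        norm_b = rng.normal(0.5, 1, 200)
        assert group_comparison(norm_a, norm_b).test_used == "t"

    def test_constant_groups_handled(self):
        res = group_comparison([1.0] * 5, [1.0] * 5)
        assert res.test_used == "wilcoxon"
        assert res.p == 1.0

    @pytest.mark.parametrize(
        "fdr,band", [(0.0005, "<0.001"), (0.01, "<0.05"), (0.2, "ns")]
    )
    def test_significance_bands(self, fdr, band):
        assert significance_band(fdr) == band

    def test_higher_group_label(self):
        res = group_comparison(
            [1.0, 1.1, 0.9, 1.2], [0.1, 0.2, 0.0, 0.15], labels=("alone", "combo")
        )
        assert res.higher_group == "alone"


class TestCotreatmentImpact:
    def test_identical_combo_not_significant(self):
        alone = [0.3, 0.31, 0.29, 0.3, 0.32]
        res = cotreatment_impact(
            alone, alone, pool_of(30), lambda d: [0.3, 0.3, 0.3, 0.31, 0.29]
        )
        assert res.direct.band == "ns"
        assert res.observed_delta == pytest.approx(0.0)

    def test_extreme_observed_delta_gives_add_one_p(self):
        """Observed shift above every pool shift with 99 pool drugs:
        pool_p = 1/100."""
        alone = [0.30, 0.31, 0.29]
        combo = [0.90, 0.91, 0.89]
        res = cotreatment_impact(
            alone, combo, pool_of(99), lambda d: [0.3, 0.31, 0.29]
        )
        assert res.pool_p == pytest.approx(1 / 100)

    def test_median_delta_gives_half(self):
        """An observed shift at the pool median lands near pool_p = 0.5."""
        alone = [0.0, 0.0, 0.0]
        combo = [0.5, 0.5, 0.5]
        shifts = np.linspace(0.0, 1.0, 101)  # median pool shift = 0.5
        drugs = pool_of(101)
        mapping = {d.name: s for d, s in zip(drugs, shifts)}
        res = cotreatment_impact(
            alone, combo, drugs, lambda d: [mapping[d.name]] * 3
        )
        assert res.pool_p == pytest.approx((51 + 1) / 102)

    def test_small_pool_rejected(self):
        with pytest.raises(EffectsError):
            cotreatment_impact([0.1] * 3, [0.2] * 3, pool_of(5), lambda d: [0.1] * 3)


class TestNullCalibration:
    def test_null_correlation_significance_rate(self):
        """With no demographic effect, the per-test significant fraction at
        alpha = 0.05 stays within the central 99% binomial band over 200
        independent cohorts."""
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(200):
            age = rng.uniform(18, 65, 50)
            ts = rng.normal(0, 1, 50)
            if stats.pearsonr(age, ts).pvalue < 0.05:
                hits += 1
        dist = stats.binom(200, 0.05)
        assert dist.ppf(0.005) <= hits <= dist.ppf(0.995)

    def test_planted_age_effect_recovered(self):
        """A linear age effect planted at n = 500 is recovered with the
        correct sign and a Strong/Moderate label in >=95% of 100 seeds."""
        good = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            age = rng.uniform(6, 17, 500)
            ts = -0.03 * age + rng.normal(0, 0.05, 500)
            res = demographic_correlation(age, ts, m_tests=4)
            if res.rho < 0 and res.category in ("Strong", "Moderate"):
                good += 1
        assert good >= 95
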