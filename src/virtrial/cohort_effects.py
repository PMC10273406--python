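"""Comparative cohort statistics.

Efficacy changes versus baseline, demographic correlations with the study's
categorical strength labels, normality-gated two-group tests, and
co-treatment impact assessed both directly and against a random drug pool.

Conventions: Pearson correlations are labelled by |ρ| bands — Strong >= 0.8,
Moderate [0.5, 0.8), Low [0.3, 0.5), Negligible < 0.3 — and overridden to
NotSignificant when the BH FDR is >= 0.05. Group comparisons use the
Jarque-Bera normality gate at alpha = 0.05 on each group: both normal gives
an unpaired two-sided t test, otherwise a Wilcoxon rank-sum; results carry
a significance band (ns, <0.05, <0.001). Empirical pool p-values use
(r + 1)/(n + 1) add-one smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .definitions import DrugDefinition
from .moa import bh_fdr, wilcoxon_rank_sum


class EffectsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# efficacy change
# ---------------------------------------------------------------------------

def efficacy_change(
    treated_tsignals,
    baseline_tsignals,
    reference_group_mean_change: float,
) -> tuple[float, float]:
    """Mean paired tSignal change and its percent of the reference group.

    delta = mean(treated - baseline); percent = 100 * delta / reference
    (so the reference group itself scores 100%).
    """
    treated = np.asarray(treated_tsignals, dtype=float)
    baseline = np.asarray(baseline_tsignals, dtype=float)
    if treated.shape != baseline.shape:
        raise EffectsError("treated and baseline must be paired per patient")
    if reference_group_mean_change == 0:
        raise EffectsError("reference mean change is 0; percentage undefined")
    delta = float(np.mean(treated - baseline))
    return delta, 100.0 * delta / reference_group_mean_change


# ---------------------------------------------------------------------------
# demographic correlations
# ---------------------------------------------------------------------------

CATEGORY_BANDS = (
    (0.8, "Strong"),
    (0.5, "Moderate"),
    (0.3, "Low"),
    (0.0, "Negligible"),
)


def categorize_correlation(rho: float, fdr: float, alpha: float = 0.05) -> str:
    """|ρ| band label, overridden to NotSignificant at FDR >= alpha."""
    if fdr >= alpha:
        return "NotSignificant"
    a = abs(rho)
    for lo, label in CATEGORY_BANDS:
        if a >= lo:
            return label
    return "Negligible"  # pragma: no cover - bands exhaust [0,1]


@dataclass
class CorrelationResult:
    rho: float
    p: float
    fdr: float
    n: int
    category: str = field(default="")

    def __post_init__(self):
        if not self.category:
            self.category = categorize_correlation(self.rho, self.fdr)


def demographic_correlation(
    values, tsignals, m_tests: int = 1
) -> CorrelationResult:
    """Pearson correlation of one demographic variable with efficacy.

    ``m_tests`` is the size of the analysis family; the single p-value is
    adjusted as min(1, p * m_tests) (the BH adjustment at rank 1, which is
    what a lone smallest p receives). For a jointly corrected table over
    several variables use :func:`demographic_correlation_table`.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(tsignals, dtype=float)
    if x.size < 3:
        raise EffectsError("need >=3 patients")
    if np.var(x) == 0 or np.var(y) == 0:
        raise EffectsError("zero variance in correlation input")
    r = stats.pearsonr(x, y)
    fdr = min(1.0, r.pvalue * m_tests)
    return CorrelationResult(float(r.statistic), float(r.pvalue), fdr, x.size)


def demographic_correlation_table(
    df: pd.DataFrame, tsignal_col: str, variables: list[str]
) -> dict[str, CorrelationResult]:
    """BH-corrected Pearson correlations for several demographic variables
    against one efficacy column, treated as one testing family."""
    raw = {}
    for var in variables:
        x = df[var].to_numpy(dtype=float)
        y = df[tsignal_col].to_numpy(dtype=float)
        r = stats.pearsonr(x, y)
        raw[var] = (float(r.statistic), float(r.pvalue), len(df))
    fdrs = bh_fdr([raw[v][1] for v in variables])
    return {
        v: CorrelationResult(raw[v][0], raw[v][1], float(f), raw[v][2])
        for v, f in zip(variables, fdrs)
    }


@dataclass
class IsolationResult:
    """Stratified correlations of one covariate with efficacy, holding the
    other covariate within quantile strata."""

    per_stratum: dict[str, list[CorrelationResult]]  # covariate -> strata
    pooled: dict[str, float]  # covariate -> n-weighted mean rho
    strata: int


def covariate_isolation(
    age, bmi, tsignals, strata: int = 3
) -> IsolationResult:
    """Correlate each covariate with efficacy inside quantile strata of the
    other (quantile-stratified correlation, not partial correlation).

    A stratum with fewer than 3 patients or zero variance is skipped. All
    stratum tests across both covariates form one BH family. ``strata = 1``
    reduces to the plain correlations.
    """
    age = np.asarray(age, dtype=float)
    bmi = np.asarray(bmi, dtype=float)
    ts = np.asarray(tsignals, dtype=float)
    if strata < 1:
        raise EffectsError("strata must be >= 1")
    pairs = {"age": (age, bmi), "bmi": (bmi, age)}
    raw: list[tuple[str, float, float, int]] = []  # covariate, rho, p, n
    for cov, (x, other) in pairs.items():
        if strata == 1:
            edges = [other.min() - 1, other.max() + 1]
        else:
            qs = np.quantile(other, np.linspace(0, 1, strata + 1))
            qs[0] -= 1e-9
            edges = qs
        for k in range(len(edges) - 1):
            mask = (other > edges[k]) & (other <= edges[k + 1])
            if mask.sum() < 3 or np.var(x[mask]) == 0 or np.var(ts[mask]) == 0:
                continue
            r = stats.pearsonr(x[mask], ts[mask])
            raw.append((cov, float(r.statistic), float(r.pvalue), int(mask.sum())))
    if not raw:
        raise EffectsError("no usable strata")
    fdrs = bh_fdr([r[2] for r in raw])
    per_stratum: dict[str, list[CorrelationResult]] = {"age": [], "bmi": []}
    for (cov, rho, p, n), f in zip(raw, fdrs):
        per_stratum[cov].append(CorrelationResult(rho, p, float(f), n))
    pooled = {}
    for cov, results in per_stratum.items():
        if results:
            w = np.array([r.n for r in results], dtype=float)
            pooled[cov] = float(
                np.sum(w * np.array([r.rho for r in results])) / w.sum()
            )
        else:
            pooled[cov] = float("nan")
    return IsolationResult(per_stratum, pooled, strata)


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

@dataclass
class GroupTestResult:
    test_used: str  # "t" | "wilcoxon"
    p: float
    fdr: float
    higher_group: str
    band: str  # "ns" | "<0.05" | "<0.001"


def _is_normal(x: np.ndarray, alpha: float = 0.05) -> bool:
    if np.var(x) == 0:
        return False
    jb = stats.jarque_bera(x)
    return bool(jb.pvalue >= alpha)


def significance_band(fdr: float) -> str:
    if fdr < 0.001:
        return "<0.001"
    if fdr < 0.05:
        return "<0.05"
    return "ns"


def group_comparison(
    group_a,
    group_b,
    m_tests: int = 1,
    labels: tuple[str, str] = ("A", "B"),
) -> GroupTestResult:
    """Normality-gated two-group efficacy comparison.

    Jarque-Bera on each group at alpha = 0.05; both normal -> two-sided
    unpaired t test, otherwise Wilcoxon rank-sum (constant groups take the
    Wilcoxon path, whose tie handling yields p = 1 for identical data). The
    family-adjusted p (min(1, p * m_tests), BH at rank 1) sets the
    significance band.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise EffectsError("need >=3 patients per group")
    if _is_normal(a) and _is_normal(b):
        test_used = "t"
        p = float(stats.ttest_ind(a, b).pvalue)
    else:
        test_used = "wilcoxon"
        p = wilcoxon_rank_sum(a, b)
    fdr = min(1.0, p * m_tests)
    higher = labels[0] if np.mean(a) >= np.mean(b) else labels[1]
    return GroupTestResult(test_used, p, fdr, higher, significance_band(fdr))


# ---------------------------------------------------------------------------
# co-treatment impact
# ---------------------------------------------------------------------------

@dataclass
class CotreatmentResult:
    direct: GroupTestResult
    pool_p: float
    observed_delta: float
    pool_deltas: np.ndarray


def cotreatment_impact(
    drug_alone_tsignals,
    combo_tsignals,
    pool_drugs: list[DrugDefinition],
    combo_tsignals_for,
    m_tests: int = 1,
) -> CotreatmentResult:
    """Does a co-treatment shift efficacy more than a random co-drug would?

    ``combo_tsignals_for`` is the pipeline context: a callable mapping a
    pool drug to the tSignal distribution of primary-drug + pool-drug
    co-administration. direct_p compares drug-alone vs the actual combo;
    pool_p is the add-one-smoothed fraction of pool co-treatments whose
    |mean tSignal shift| is at least the observed one.
    """
    if len(pool_drugs) < 20:
        raise EffectsError("pool must contain at least 20 drugs")
    alone = np.asarray(drug_alone_tsignals, dtype=float)
    combo = np.asarray(combo_tsignals, dtype=float)
    direct = group_comparison(alone, combo, m_tests, labels=("alone", "combo"))
    observed = abs(float(np.mean(combo) - np.mean(alone)))
    deltas = []
    for pd_drug in pool_drugs:
        pool_ts = np.asarray(combo_tsignals_for(pd_drug), dtype=float)
        deltas.append(abs(float(np.mean(pool_ts) - np.mean(alone))))
    deltas = np.array(deltas)
    pool_p = (np.sum(deltas >= observed) + 1.0) / (len(deltas) + 1.0)
    return CotreatmentResult(direct, float(pool_p), observed, deltas)
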