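"""Virtual cohort construction.

Builds randomized virtual patient populations that honour the study design's
hard quotas (profile minima, main-group minimum, power-derived minimum
cohort size) and match the reference demographic distributions within a
relative tolerance (the study's inclusion/exclusion criterion, 5% by
default).

The minimum cohort size is derived from case/control expression data: the
per-sample pooled disease-gene score is reduced to a standardized effect
size, and the smallest per-group n reaching the target power under a
two-sample t test is found by integer search over the noncentral-t power
function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .definitions import ComorbidityProfile
from .synthetic import CohortBlock, ExpressionMatrix, ReferenceTable

#: Study constant: minimum population size per cohort derived from the
#: expression power analysis (95% power to separate cases from controls).
STUDY_POWER_MINIMUM = 71
#: Study quotas: >=100 virtual patients per comorbidity profile and >=500 in
#: the main (comorbidity-free) group, totalling 1,300 per population.
STUDY_POPULATION_SIZE = 1300
STUDY_PROFILE_MINIMUM = 100
STUDY_MAIN_GROUP_MINIMUM = 500
STUDY_TOLERANCE = 0.05


class CohortError(ValueError):
    """Raised when a cohort request is infeasible or validation fails."""


@dataclass
class VirtualPatient:
    id: str
    cohort: str  # child | adolescent | adult
    age: float
    sex: str  # female | male
    weight: float  # kg
    height: float  # cm
    profile: str = "none"

    @property
    def bmi(self) -> float:
        return self.weight / (self.height / 100.0) ** 2


@dataclass
class CohortSpec:
    """Cohort request: total size, quotas, tolerance, and the power floor."""

    total_size: int
    profile_quotas: dict[str, int] = field(default_factory=dict)
    main_group_minimum: int = 0
    tolerance: float = STUDY_TOLERANCE
    power_minimum: int = STUDY_POWER_MINIMUM
    population: str = "adult"  # adult | child_adolescent

    def __post_init__(self):
        if not 0.0 < self.tolerance < 1.0:
            raise CohortError("tolerance must be in (0,1)")
        minima = sum(self.profile_quotas.values()) + self.main_group_minimum
        if minima > self.total_size:
            raise CohortError(
                f"quota minima ({minima}) exceed total size ({self.total_size})"
            )

    @classmethod
    def study_default(cls, population: str = "adult") -> "CohortSpec":
        """The study's per-population spec: 8 x 100 profile quota + 500 main
        group = 1,300 patients."""
        from .definitions import load_profile_catalog

        quotas = {
            p["name"]: STUDY_PROFILE_MINIMUM
            for p in load_profile_catalog()
            if p["name"] != "none"
        }
        return cls(
            total_size=STUDY_POPULATION_SIZE,
            profile_quotas=quotas,
            main_group_minimum=STUDY_MAIN_GROUP_MINIMUM,
            population=population,
        )


# ---------------------------------------------------------------------------
# power-derived minimum cohort size
# ---------------------------------------------------------------------------

def two_sample_t_power(d: float, n: int, alpha: float = 0.05) -> float:
    """Power of the two-sided two-sample t test at per-group size n,
    standardized effect d, via the noncentral t distribution."""
    df = 2 * n - 2
    ncp = abs(d) * math.sqrt(n / 2.0)
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(
        1.0 - stats.nct.cdf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp)
    )


def required_n(d: float, power_target: float = 0.95, alpha: float = 0.05) -> int:
    """Smallest per-group n with two-sample t power >= power_target."""
    if d == 0 or not math.isfinite(d):
        raise CohortError("power target unattainable at zero effect size")
    n = 2
    while two_sample_t_power(d, n, alpha) < power_target:
        n += max(1, n // 10)
        if n > 10_000_000:  # pragma: no cover - defensive
            raise CohortError("power target unattainable")
    # walk back to the exact threshold after the accelerated search
    while n > 2 and two_sample_t_power(d, n - 1, alpha) >= power_target:
        n -= 1
    return n


def minimum_cohort_size(
    expr: ExpressionMatrix, power_target: float = 0.95, alpha: float = 0.05
) -> int:
    """Minimum per-group population size able to distinguish pathological
    from healthy individuals at the target power.

    The per-sample expression score (mean over disease genes) is reduced to
    a pooled standardized effect size; the returned n is the smallest
    per-group size at which the two-sample t test attains ``power_target``.
    """
    case, ctrl = expr.pooled_scores()
    n1, n2 = len(case), len(ctrl)
    sp2 = (
        (n1 - 1) * np.var(case, ddof=1) + (n2 - 1) * np.var(ctrl, ddof=1)
    ) / (n1 + n2 - 2)
    if sp2 <= 0:
        raise CohortError("degenerate expression scores (zero variance)")
    d = float((np.mean(case) - np.mean(ctrl)) / math.sqrt(sp2))
    if d == 0:
        raise CohortError("power target unattainable at zero effect size")
    return required_n(d, power_target, alpha)


# ---------------------------------------------------------------------------
# cohort sampling
# ---------------------------------------------------------------------------

def _sample_block(
    rng: np.random.Generator, block: CohortBlock, ids: list[str], profiles: list[str]
) -> list[VirtualPatient]:
    n = len(ids)
    ages = rng.uniform(block.age_min, block.age_max, size=n)
    sexes = np.where(rng.random(n) < block.sex_female_prop, "female", "male")
    h_mean = block.height_at_min + block.height_slope * (ages - block.age_min)
    w_mean = block.weight_at_min + block.weight_slope * (ages - block.age_min)
    # truncate at 3 sd to keep morphometrics physiologic
    heights = h_mean + block.height_sd * stats.truncnorm.rvs(
        -3, 3, size=n, random_state=rng
    )
    weights = w_mean + block.weight_sd * stats.truncnorm.rvs(
        -3, 3, size=n, random_state=rng
    )
    return [
        VirtualPatient(
            ids[i], block.name, float(ages[i]), str(sexes[i]),
            float(weights[i]), float(heights[i]), profiles[i],
        )
        for i in range(n)
    ]


def _profile_assignment(spec: CohortSpec) -> list[str]:
    counts = dict(spec.profile_quotas)
    assigned = sum(counts.values())
    counts["none"] = max(spec.main_group_minimum, spec.total_size - assigned)
    overflow = sum(counts.values()) - spec.total_size
    if overflow > 0:
        raise CohortError("infeasible quotas for requested total size")
    labels = []
    for name, k in counts.items():
        labels.extend([name] * k)
    return labels


def sample_cohort(
    reference: ReferenceTable,
    spec: CohortSpec,
    seed: int,
    max_retries: int = 50,
) -> list[VirtualPatient]:
    """Sample a virtual cohort honouring quotas and the reference tolerance.

    Hard postconditions: exactly ``spec.total_size`` patients; every profile
    quota and the main-group minimum met; per-variable summary statistics
    within ``spec.tolerance`` (relative) of the reference table. A request
    below ``spec.power_minimum`` is rejected outright. Resamples the whole
    cohort up to ``max_retries`` times before failing with the offending
    variable named.
    """
    if spec.total_size < spec.power_minimum:
        raise CohortError(
            f"requested cohort size {spec.total_size} is below the "
            f"power-derived minimum of {spec.power_minimum} patients"
        )
    if spec.population == "adult":
        blocks = [reference.blocks["adult"]]
    elif spec.population == "child_adolescent":
        blocks = [reference.blocks["child"], reference.blocks["adolescent"]]
    else:
        raise CohortError(f"unknown population {spec.population!r}")
    labels = _profile_assignment(spec)
    rng = np.random.default_rng(seed)
    last_fail = "unknown"
    ids = [f"p{i:05d}" for i in range(len(labels))]
    for _ in range(max_retries):
        block_of = rng.integers(len(blocks), size=len(labels))
        patients = []
        for bi, block in enumerate(blocks):
            idx = [i for i in range(len(labels)) if block_of[i] == bi]
            patients.extend(
                _sample_block(
                    rng, block, [ids[i] for i in idx], [labels[i] for i in idx]
                )
            )
        patients.sort(key=lambda p: p.id)
        report = validate_cohort(patients, reference, spec.tolerance)
        if report.passed:
            return patients
        last_fail = ", ".join(report.failures())
    raise CohortError(
        f"reference match unachievable after {max_retries} retries "
        f"(failing variables: {last_fail})"
    )


@dataclass
class ValidationReport:
    """Per-variable pass/fail against the reference distributions."""

    rows: pd.DataFrame  # block, variable, observed, reference, rel_dev, ok
    tolerance: float

    @property
    def passed(self) -> bool:
        return bool(self.rows["ok"].all())

    def failures(self) -> list[str]:
        bad = self.rows[~self.rows["ok"]]
        return [f"{b}/{v}" for b, v in zip(bad["block"], bad["variable"])]


def validate_cohort(
    cohort: list[VirtualPatient],
    reference: ReferenceTable,
    tolerance: float = STUDY_TOLERANCE,
) -> ValidationReport:
    """Check cohort summary statistics against the reference table.

    For every age block present in the cohort, the mean age, height, weight,
    BMI and the female proportion must lie within ``tolerance`` relative
    deviation of their reference expectations.
    """
    if not cohort:
        raise CohortError("empty cohort")
    df = cohort_to_frame(cohort)
    rows = []
    for name, grp in df.groupby("cohort"):
        block = reference.blocks[str(name)]
        exp = {
            "age": block.expected_age(),
            "height": block.expected_height(),
            "weight": block.expected_weight(),
            "bmi": block.expected_weight() / (block.expected_height() / 100) ** 2,
            "female_prop": block.sex_female_prop,
        }
        obs = {
            "age": grp["age"].mean(),
            "height": grp["height"].mean(),
            "weight": grp["weight"].mean(),
            "bmi": grp["bmi"].mean(),
            "female_prop": (grp["sex"] == "female").mean(),
        }
        for var, ref in exp.items():
            o = obs[var]
            rel = abs(o - ref) / abs(ref) if ref != 0 else abs(o)
            rows.append(
                dict(block=name, variable=var, observed=o, reference=ref,
                     rel_dev=rel, ok=rel <= tolerance)
            )
    return ValidationReport(pd.DataFrame(rows), tolerance)


def cohort_to_frame(cohort: list[VirtualPatient]) -> pd.DataFrame:
    """Cohort as a tidy DataFrame (fixed column order, CSV-friendly)."""
    return pd.DataFrame(
        [
            dict(
                id=p.id, cohort=p.cohort, age=p.age, sex=p.sex,
                weight=p.weight, height=p.height, bmi=p.bmi, profile=p.profile,
            )
            for p in cohort
        ],
        columns=["id", "cohort", "age", "sex", "weight", "height", "bmi", "profile"],
    )


def frame_to_cohort(df: pd.DataFrame) -> list[VirtualPatient]:
    return [
        VirtualPatient(
            str(r.id), str(r.cohort), float(r.age), str(r.sex),
            float(r.weight), float(r.height), str(r.profile),
        )
        for r in df.itertuples()
    ]
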