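"""Outcome statistics for mechanism-of-action comparison.

The efficacy proxy is the *tSignal*: the mean predicted protein activity
over the disease protein set, sign-adjusted so that positive values mean
disease reversion (a protein activated in disease counts by its negated
activity). A disease protein is *reverted* when its predicted activity
exceeds 0.5 in magnitude in the direction opposite its disease activation
sign; *differentially reverted* proteins additionally separate the two
drugs' solution ensembles by a Wilcoxon rank-sum test under BH-FDR control,
and *most strongly reverted* proteins are those a single activity threshold
classifies with 100% accuracy (the two drugs' activity ranges are
disjoint).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .definitions import DiseaseDefinition

REVERSION_THRESHOLD = 0.5


class MoAError(ValueError):
    pass


@dataclass
class TSignalResult:
    value: float
    per_motive: dict[str, float]
    n_proteins: int


def tsignal(
    activity: dict[str, float], disease: DiseaseDefinition
) -> TSignalResult:
    """Sign-adjusted mean disease-set activity (the efficacy proxy).

    value = (1/|D|) * sum_{p in D} (-disease_sign(p)) * activity(p) over the
    distinct (protein, sign) members of the disease definition; per-motive
    values are computed the same way within each motive.
    """
    members = disease.members()
    if not members:
        raise MoAError("empty disease set")
    missing = [g for g, _ in members if g not in activity]
    if missing:
        raise MoAError(f"activity vector lacks disease proteins: {missing}")
    value = float(np.mean([-s * activity[g] for g, s in members]))
    per_motive = {
        m.name: float(
            np.mean([-s * activity[p.gene_symbol] for p, s in m.members])
        )
        for m in disease.motives
    }
    return TSignalResult(value, per_motive, len(members))


def reverted_proteins(
    mean_activity: dict[str, float],
    disease: DiseaseDefinition,
    threshold: float = REVERSION_THRESHOLD,
) -> set[str]:
    """Disease proteins whose activity opposes the disease sign with
    magnitude strictly above the threshold."""
    if not 0.0 < threshold < 1.0:
        raise MoAError("threshold must be in (0,1)")
    out = set()
    for gene, sign in disease.members():
        a = mean_activity.get(gene)
        if a is None:
            continue
        if abs(a) > threshold and np.sign(a) == -sign:
            out.add(gene)
    return out


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum machinery
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact distribution when both groups have <= 8 observations and no ties;
    normal approximation with tie correction otherwise. Degenerate all-tied
    inputs give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (max(len(x), len(y)) <= 8 and no_ties) else "asymptotic"
    return float(
        stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _per_protein_values(activities: list[dict[str, float]], gene: str):
    return np.array([a[gene] for a in activities])


def differentially_reverted(
    activities_a: list[dict[str, float]],
    activities_b: list[dict[str, float]],
    disease: DiseaseDefinition,
    alpha: float = 0.05,
    threshold: float = REVERSION_THRESHOLD,
) -> pd.DataFrame:
    """Per-protein drug comparison over the reverted-by-either candidates.

    For each protein reverted by either drug (on ensemble-mean activities),
    a two-sided Wilcoxon rank-sum test compares the per-solution activity
    values of the two drugs; BH FDR is applied across proteins. Returns a
    table (protein, p, fdr, significant) sorted by FDR; all-tied proteins
    appear with FDR 1 rather than being dropped.
    """
    if len(activities_a) < 2 or len(activities_b) < 2:
        raise MoAError("need >=2 activity vectors per drug")
    mean_a = {g: np.mean([a[g] for a in activities_a]) for g in activities_a[0]}
    mean_b = {g: np.mean([b[g] for b in activities_b]) for g in activities_b[0]}
    candidates = sorted(
        reverted_proteins(mean_a, disease, threshold)
        | reverted_proteins(mean_b, disease, threshold)
    )
    rows = []
    for gene in candidates:
        p = wilcoxon_rank_sum(
            _per_protein_values(activities_a, gene),
            _per_protein_values(activities_b, gene),
        )
        rows.append((gene, p))
    if not rows:
        return pd.DataFrame(columns=["protein", "p", "fdr", "significant"])
    df = pd.DataFrame(rows, columns=["protein", "p"])
    df["fdr"] = bh_fdr(df["p"].to_numpy())
    df["significant"] = df["fdr"] < alpha
    return df.sort_values(["fdr", "protein"]).reset_index(drop=True)


def most_strongly_reverted(
    candidates,
    activities_a: list[dict[str, float]],
    activities_b: list[dict[str, float]],
) -> set[str]:
    """Candidates whose per-solution activity ranges are disjoint between
    drugs, i.e. a single threshold classifies the two drugs' solutions with
    100% accuracy."""
    out = set()
    for gene in candidates:
        va = _per_protein_values(activities_a, gene)
        vb = _per_protein_values(activities_b, gene)
        if va.max() < vb.min() or vb.max() < va.min():
            out.add(gene)
    return out


def motive_counts(
    reverted: set[str], disease: DiseaseDefinition
) -> dict[str, int]:
    """Reverted-protein counts per motive (multi-motive proteins count in
    each motive they belong to)."""
    return {
        m.name: sum(1 for p, _ in m.members if p.gene_symbol in reverted)
        for m in disease.motives
    }


@dataclass
class RevertedProteinReport:
    """The full reverted-protein taxonomy for one drug pair.

    Satisfies the nesting invariant
    most_strongly ⊆ differentially ⊆ reverted-by-either.
    """

    reverted_a: set[str]
    reverted_b: set[str]
    differential: pd.DataFrame
    most_strongly: set[str]

    def __post_init__(self):
        either = self.reverted_a | self.reverted_b
        diff = set(self.differential.loc[self.differential["significant"], "protein"])
        if not diff <= either:
            raise MoAError("differentially reverted set escapes the candidates")
        if not self.most_strongly <= diff:
            raise MoAError("most-strongly set escapes the differential set")


def reverted_protein_report(
    activities_a: list[dict[str, float]],
    activities_b: list[dict[str, float]],
    disease: DiseaseDefinition,
    alpha: float = 0.05,
    threshold: float = REVERSION_THRESHOLD,
) -> RevertedProteinReport:
    """Run the full taxonomy: reverted -> differentially -> most strongly."""
    mean_a = {g: np.mean([a[g] for a in activities_a]) for g in activities_a[0]}
    mean_b = {g: np.mean([b[g] for b in activities_b]) for g in activities_b[0]}
    rev_a = reverted_proteins(mean_a, disease, threshold)
    rev_b = reverted_proteins(mean_b, disease, threshold)
    diff = differentially_reverted(
        activities_a, activities_b, disease, alpha, threshold
    )
    sig = list(diff.loc[diff["significant"], "protein"])
    strong = most_strongly_reverted(sig, activities_a, activities_b)
    return RevertedProteinReport(rev_a, rev_b, diff, strong)


def enrich(
    protein_set: set[str],
    annotations: dict[str, set[str]],
    universe: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of annotation terms.

    Upper-tail p for the overlap of ``protein_set`` with each term within
    ``universe``, BH-corrected across terms. Returns (term, overlap, p, fdr,
    significant).
    """
    if not universe:
        raise MoAError("empty universe")
    if not protein_set <= universe:
        raise MoAError("protein_set must be a subset of the universe")
    m_u = len(universe)
    n_q = len(protein_set)
    rows = []
    for term, members in annotations.items():
        members_in = members & universe
        k = len(protein_set & members_in)
        p = float(stats.hypergeom.sf(k - 1, m_u, len(members_in), n_q))
        rows.append((term, k, p))
    df = pd.DataFrame(rows, columns=["term", "overlap", "p"])
    df["fdr"] = bh_fdr(df["p"].to_numpy())
    df["significant"] = df["fdr"] < alpha
    return df.sort_values(["fdr", "term"]).reset_index(drop=True)


def parse_gmt(text: str) -> dict[str, set[str]]:
    """Parse GMT-format annotation terms (term, description, genes...)."""
    out = {}
    for line in text.splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise MoAError(f"malformed GMT line: {line!r}")
        out[parts[0]] = set(parts[2:])
    return out
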