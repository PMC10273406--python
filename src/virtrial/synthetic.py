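"""Synthetic generators for every study input that came from proprietary or
external sources: the protein network, the disease embedding, case/control
expression data, reference demographics, a random drug pool, and the
restriction set used to train solution ensembles.

Every generator is a pure function of (configuration, seed). The statistical
structure is deliberately simple and analytically checkable: a directed
Erdős–Rényi network with Rademacher signs and |N(0,1)| weights, and a
Gaussian mean-shift expression model on the disease genes only, so the
power computation downstream has a closed-form oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .definitions import (
    MOTIVE_NAMES,
    ComorbidityProfile,
    DefinitionError,
    DiseaseDefinition,
    DrugDefinition,
    Motive,
    Network,
    ProteinRef,
    Target,
    load_profile_catalog,
)


@dataclass
class ExpressionMatrix:
    """genes x samples expression table with case/control labels."""

    values: pd.DataFrame  # genes x samples
    labels: pd.Series  # sample -> "case" | "control"
    disease_genes: list[str]

    def __post_init__(self):
        counts = self.labels.value_counts()
        if counts.get("case", 0) < 2 or counts.get("control", 0) < 2:
            raise ValueError("need >=2 samples per class")
        if self.values.isna().any().any():
            raise ValueError("expression matrix has missing values")

    def pooled_scores(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-sample mean over disease genes, split (case, control)."""
        score = self.values.loc[self.disease_genes].mean(axis=0)
        return (
            score[self.labels == "case"].to_numpy(),
            score[self.labels == "control"].to_numpy(),
        )


@dataclass
class CohortBlock:
    """Reference distribution for one age block of one population."""

    name: str  # child | adolescent | adult
    age_min: float
    age_max: float
    sex_female_prop: float
    height_at_min: float  # cm at age_min
    height_slope: float  # cm per year within the block
    height_sd: float
    weight_at_min: float  # kg at age_min
    weight_slope: float  # kg per year
    weight_sd: float

    def __post_init__(self):
        if self.age_min >= self.age_max:
            raise ValueError(f"inverted age bounds in block {self.name!r}")
        if not 0.0 <= self.sex_female_prop <= 1.0:
            raise ValueError(
                f"sex proportion {self.sex_female_prop} outside [0,1] "
                f"in block {self.name!r}"
            )

    def expected_age(self) -> float:
        return 0.5 * (self.age_min + self.age_max)

    def expected_height(self) -> float:
        return self.height_at_min + self.height_slope * (
            self.expected_age() - self.age_min
        )

    def expected_weight(self) -> float:
        return self.weight_at_min + self.weight_slope * (
            self.expected_age() - self.age_min
        )


@dataclass
class ReferenceTable:
    """Per-block demographic reference distributions for cohort generation."""

    blocks: dict[str, CohortBlock]

    def __post_init__(self):
        names = set(self.blocks)
        if {"child", "adolescent"} <= names:
            if self.blocks["child"].age_max >= self.blocks["adolescent"].age_min:
                raise ValueError("child and adolescent age ranges overlap")


#: Default block specification: children 6-12, adolescents 13-17, adults 18+,
#: with growth-curve-like height/weight trends inside the pediatric blocks.
DEFAULT_COHORT_SPEC: dict[str, dict] = {
    "child": dict(
        age_min=6, age_max=12, sex_female_prop=0.32,
        height_at_min=115.0, height_slope=5.5, height_sd=5.0,
        weight_at_min=21.0, weight_slope=3.3, weight_sd=3.0,
    ),
    "adolescent": dict(
        age_min=13, age_max=17, sex_female_prop=0.35,
        height_at_min=156.0, height_slope=3.0, height_sd=7.0,
        weight_at_min=46.0, weight_slope=3.5, weight_sd=6.0,
    ),
    "adult": dict(
        age_min=18, age_max=65, sex_female_prop=0.45,
        height_at_min=170.0, height_slope=0.0, height_sd=9.0,
        weight_at_min=72.0, weight_slope=0.0, weight_sd=12.0,
    ),
}


def generate_reference_demographics(
    cohort_spec: dict[str, dict] | None = None, seed: int = 0
) -> ReferenceTable:
    """Build the demographic reference table from a block specification.

    The default specification mirrors the study's cohort structure —
    children (6-12 years), adolescents (13-17), adults — with European-like
    anthropometric summaries. Deterministic; ``seed`` is accepted for
    interface symmetry with the other generators.
    """
    spec = cohort_spec if cohort_spec is not None else DEFAULT_COHORT_SPEC
    blocks = {name: CohortBlock(name=name, **params) for name, params in spec.items()}
    return ReferenceTable(blocks)


def generate_network(
    n_proteins: int,
    edge_density: float,
    seed: int,
    include: list[str] | None = None,
) -> Network:
    """Random directed signed network: Erdős–Rényi G(n, p) substrate.

    Edge signs are Rademacher(1/2) and weights |N(0,1)|. The graph is
    redrawn (up to 100 attempts) until weakly connected. ``include`` names
    nodes that must exist (e.g. the study drugs' target genes); remaining
    nodes are labelled G001, G002, ...
    """
    if n_proteins < 10:
        raise ValueError("n_proteins must be >= 10")
    if not 0.0 < edge_density < 1.0:
        raise ValueError("edge_density must be in (0,1)")
    include = list(include or [])
    if len(include) > n_proteins:
        raise ValueError("more required nodes than n_proteins")
    names = include + [
        f"G{i:03d}" for i in range(1, n_proteins - len(include) + 1)
    ]
    rng = np.random.default_rng(seed)
    for _ in range(100):
        g = nx.DiGraph()
        g.add_nodes_from(names)
        mask = rng.random((n_proteins, n_proteins)) < edge_density
        np.fill_diagonal(mask, False)
        src, dst = np.nonzero(mask)
        signs = rng.choice([-1, 1], size=src.size)
        weights = np.abs(rng.standard_normal(src.size))
        weights[weights < 1e-6] = 1e-6
        for i, j, s, w in zip(src, dst, signs, weights):
            g.add_edge(names[i], names[j], sign=int(s), weight=float(w))
        if g.number_of_edges() > 0 and nx.is_weakly_connected(g):
            return Network(g)
    raise ValueError(
        f"could not draw a weakly connected graph at density {edge_density}"
    )


def generate_disease_embedding(
    network: Network, motive_sizes: tuple[int, int, int, int], seed: int
) -> DiseaseDefinition:
    """Embed a four-motive disease definition into the network.

    Members are drawn without replacement across motives (so motives are
    disjoint) and get random +/-1 disease activation signs.
    """
    if len(motive_sizes) != 4:
        raise ValueError("exactly four motive sizes required")
    total = sum(motive_sizes)
    if total > network.n_nodes:
        raise ValueError(
            f"motive sizes sum to {total} > {network.n_nodes} network nodes"
        )
    if any(s < 1 for s in motive_sizes):
        raise ValueError("every motive needs at least one member")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(network.nodes, size=total, replace=False)
    signs = rng.choice([-1, 1], size=total)
    motives, k = [], 0
    for name, size in zip(MOTIVE_NAMES, motive_sizes):
        members = [
            (ProteinRef(str(chosen[k + i])), int(signs[k + i])) for i in range(size)
        ]
        motives.append(Motive(name, members))
        k += size
    return DiseaseDefinition("synthetic ADHD", motives)


def generate_expression_matrix(
    n_case: int,
    n_control: int,
    effect_size: float,
    n_genes: int,
    seed: int,
    n_disease_genes: int = 20,
) -> ExpressionMatrix:
    """Case/control expression with a mean shift on the disease genes only.

    Controls are N(0,1) everywhere; cases are shifted by ``effect_size`` on
    the first ``n_disease_genes`` genes, so the pooled disease-gene score is
    N(effect_size, 1/k) for cases vs N(0, 1/k) for controls and the
    downstream two-sample power analysis has a closed form.
    """
    if n_case < 2 or n_control < 2:
        raise ValueError("need >=2 samples per class")
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    if n_disease_genes > n_genes:
        raise ValueError("n_disease_genes exceeds n_genes")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:03d}" for i in range(1, n_genes + 1)]
    samples = [f"case{i}" for i in range(n_case)] + [
        f"ctrl{i}" for i in range(n_control)
    ]
    x = rng.standard_normal((n_genes, n_case + n_control))
    x[:n_disease_genes, :n_case] += effect_size
    labels = pd.Series(
        ["case"] * n_case + ["control"] * n_control, index=samples, name="label"
    )
    return ExpressionMatrix(
        pd.DataFrame(x, index=genes, columns=samples), labels, genes[:n_disease_genes]
    )


def generate_drug_pool(
    network: Network,
    n_drugs: int,
    target_size_range: tuple[int, int],
    seed: int,
) -> list[DrugDefinition]:
    """Random drug pool standing in for a drug database (DrugBank-like).

    Each pool drug draws a uniform target-set size in ``target_size_range``,
    uniform random node targets without replacement, and random +/-1 effects.
    """
    if n_drugs < 1:
        raise ValueError("n_drugs must be >= 1")
    lo, hi = target_size_range
    if lo < 1 or hi < lo:
        raise ValueError("invalid target_size_range")
    if hi > network.n_nodes:
        raise ValueError("target_size_range exceeds node count")
    rng = np.random.default_rng(seed)
    pool = []
    for i in range(n_drugs):
        size = int(rng.integers(lo, hi + 1))
        genes = rng.choice(network.nodes, size=size, replace=False)
        effects = rng.choice([-1, 1], size=size)
        targets = [
            Target(ProteinRef(str(g)), int(e)) for g, e in zip(genes, effects)
        ]
        pool.append(DrugDefinition(f"pool{i:04d}", targets))
    return pool


def generate_comorbidity_profiles(
    network: Network,
    seed: int,
    size_range: tuple[int, int] = (3, 6),
    exclude: set[str] | None = None,
) -> dict[str, ComorbidityProfile]:
    """Synthetic molecular definitions for the study's comorbidity profiles.

    Profile names and co-treatment lists come from the shipped catalog; each
    non-"none" profile gets a random signed protein set sampled from network
    nodes (optionally excluding e.g. disease genes).
    """
    rng = np.random.default_rng(seed)
    candidates = [n for n in network.nodes if n not in (exclude or set())]
    out = {}
    for entry in load_profile_catalog():
        name = entry["name"]
        if name == "none":
            out[name] = ComorbidityProfile(name, [], list(entry["co_treatments"]))
            continue
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        genes = rng.choice(candidates, size=size, replace=False)
        signs = rng.choice([-1, 1], size=size)
        out[name] = ComorbidityProfile(
            name,
            [(ProteinRef(str(g)), int(s)) for g, s in zip(genes, signs)],
            list(entry["co_treatments"]),
        )
    return out


@dataclass
class Restriction:
    """One training constraint: a stimulus and its required response band.

    The stimulus is a known drug's full-intensity signed target set; the
    required band brackets the sign-adjusted disease tSignal the trained
    model must produce for that drug, centred on its scaled clinical
    efficacy.
    """

    stimulus: dict[str, float]
    response: list[tuple[str, int]]  # (gene, disease_sign)
    band: tuple[float, float]
    band_half_width: float = 0.15

    def __post_init__(self):
        lo, hi = self.band
        if lo > hi:
            raise ValueError("band lower bound exceeds upper bound")
        if lo < -1.0 or hi > 1.0:
            raise ValueError("band must lie within [-1, 1]")
        for v in self.stimulus.values():
            if not -1.0 <= v <= 1.0:
                raise ValueError("stimulus intensities must lie in [-1, 1]")


def generate_restrictions(
    network: Network,
    disease: DiseaseDefinition,
    training_drugs: list[tuple[DrugDefinition, float]],
    seed: int = 0,
    band_half_width: float = 0.15,
    efficacy_scale: float = 0.3,
) -> list[Restriction]:
    """Training restrictions from known drugs' clinical efficacies.

    Each drug contributes one restriction: stimulus = its signed target set
    at full intensity; required sign-adjusted tSignal within
    ``efficacy * efficacy_scale ± band_half_width`` (clipped to [-1,1]).
    ``efficacy_scale`` maps the [0,1] clinical-efficacy scale onto the
    tSignal magnitudes reachable on the synthetic network.
    """
    response = disease.members()
    out = []
    for drug, efficacy in training_drugs:
        if not 0.0 <= efficacy <= 1.0:
            raise ValueError(
                f"efficacy {efficacy} for {drug.name!r} outside [0,1]"
            )
        missing = [g for g in drug.target_genes if g not in network._node_index]
        if missing:
            raise DefinitionError(
                f"training drug {drug.name!r} targets absent from network: {missing}"
            )
        stimulus = {
            g: float(np.clip(e, -1.0, 1.0)) for g, e in drug.signed_targets().items()
        }
        center = efficacy * efficacy_scale
        band = (
            max(-1.0, center - band_half_width),
            min(1.0, center + band_half_width),
        )
        out.append(Restriction(stimulus, response, band, band_half_width))
    return out
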