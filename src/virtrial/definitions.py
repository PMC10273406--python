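"""Data model and file I/O for virtual drugs, disease motives, comorbidity
profiles, and signed protein-interaction networks.

A *virtual drug* is a named set of signed protein targets (+1 activation, -1
inhibition) plus a reference to a pharmacokinetic parameter record. A
*disease definition* groups signed proteins into named "motives" — the
biological sub-processes whose joint dysregulation constitutes the disease;
the default ADHD definition has exactly four. The *network* is a directed
graph whose edges carry a sign and a positive weight; it is the substrate on
which drug stimuli are propagated.

File dialects are deliberately plain: tab-separated tables for drug targets,
4-column TSV edge lists for networks, and YAML for motives and comorbidity
profiles, so every fixture is diff-able.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from importlib import resources

import networkx as nx
import yaml

#: Canonical names of the four ADHD pathophysiology motives.
MOTIVE_NAMES = (
    "neurotransmitter imbalance",
    "neuroinflammation",
    "circadian system imbalance",
    "altered neural viability",
)


class DefinitionError(ValueError):
    """Raised when a drug/disease/network definition violates its invariants."""


@dataclass(frozen=True)
class ProteinRef:
    """A protein identified by its (uppercase) gene symbol."""

    gene_symbol: str
    display_name: str = ""

    def __post_init__(self):
        if not self.gene_symbol:
            raise DefinitionError("gene_symbol must be nonempty")


@dataclass(frozen=True)
class Target:
    """One drug-protein interaction: +1 activates, -1 inhibits.

    ``conflict`` marks entries produced by merging co-treatments with opposite
    signs at the same protein; such pairs are resolved downstream by summing
    signed intensities at stimulus-construction time.
    """

    protein: ProteinRef
    effect: int
    conflict: bool = False

    def __post_init__(self):
        if self.effect not in (-1, 1):
            raise DefinitionError(
                f"effect must be +1 or -1, got {self.effect!r} for "
                f"{self.protein.gene_symbol}"
            )


@dataclass
class DrugDefinition:
    """A virtual drug: signed protein-target set plus a PK parameter handle."""

    name: str
    targets: list[Target]
    pk_ref: str = ""

    def __post_init__(self):
        if not self.targets:
            raise DefinitionError(f"drug {self.name!r} has no targets")
        seen: dict[str, int] = {}
        for t in self.targets:
            g = t.protein.gene_symbol
            if g in seen:
                if not t.conflict:
                    raise DefinitionError(
                        f"drug {self.name!r} lists protein {g} twice"
                    )
            seen[g] = t.effect

    @property
    def target_genes(self) -> list[str]:
        return [t.protein.gene_symbol for t in self.targets]

    def signed_targets(self) -> dict[str, int]:
        """gene -> effect; conflicting pairs sum to 0."""
        out: dict[str, int] = {}
        for t in self.targets:
            out[t.protein.gene_symbol] = out.get(t.protein.gene_symbol, 0) + t.effect
        return out


@dataclass
class Motive:
    """One named disease sub-process: a set of proteins with disease signs."""

    name: str
    members: list[tuple[ProteinRef, int]]

    def __post_init__(self):
        if not self.members:
            raise DefinitionError(f"motive {self.name!r} is empty")
        seen = set()
        for p, s in self.members:
            if s not in (-1, 1):
                raise DefinitionError(
                    f"invalid disease sign {s!r} for {p.gene_symbol} "
                    f"in motive {self.name!r}"
                )
            if p.gene_symbol in seen:
                raise DefinitionError(
                    f"protein {p.gene_symbol} repeated in motive {self.name!r}"
                )
            seen.add(p.gene_symbol)


@dataclass
class DiseaseDefinition:
    """A disease as named motives of signed proteins.

    The default ADHD definition carries the four canonical motives; arbitrary
    motive counts are permitted for ad-hoc disease sets.
    """

    name: str
    motives: list[Motive]

    def __post_init__(self):
        if not self.motives:
            raise DefinitionError("disease must have at least one motive")

    def members(self) -> list[tuple[str, int]]:
        """Distinct (gene, disease_sign) pairs over the union of motives."""
        out: list[tuple[str, int]] = []
        seen = set()
        for m in self.motives:
            for p, s in m.members:
                key = (p.gene_symbol, s)
                if key not in seen:
                    seen.add(key)
                    out.append(key)
        return out

    def genes(self) -> set[str]:
        return {g for g, _ in self.members()}


@dataclass
class ComorbidityProfile:
    """A patient class: molecular definition plus typical co-treatments.

    The "none" profile (main ADHD group) is the only one allowed an empty
    molecular definition.
    """

    name: str
    molecular_definition: list[tuple[ProteinRef, int]] = field(default_factory=list)
    co_treatments: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.name != "none" and not self.molecular_definition:
            raise DefinitionError(
                f"profile {self.name!r} needs a molecular definition"
            )
        for _, s in self.molecular_definition:
            if s not in (-1, 1):
                raise DefinitionError(f"invalid sign {s!r} in profile {self.name!r}")


class Network:
    """Directed signed weighted protein network.

    Thin wrapper over a :class:`networkx.DiGraph` with per-edge ``sign``
    (+1/-1) and positive ``weight`` attributes. Exposes a stable, sorted edge
    list so that external weight vectors (trained solutions) can be aligned
    to edges reproducibly.
    """

    def __init__(self, graph: nx.DiGraph):
        for u, v, d in graph.edges(data=True):
            if u == v:
                raise DefinitionError(f"self-loop at {u}")
            if d.get("sign") not in (-1, 1):
                raise DefinitionError(f"edge {u}->{v} has invalid sign")
            if not d.get("weight", 0) > 0:
                raise DefinitionError(f"edge {u}->{v} has non-positive weight")
        self.graph = graph
        self.nodes: list[str] = sorted(graph.nodes)
        self.edge_list: list[tuple[str, str]] = sorted(graph.edges)
        self._node_index = {n: i for i, n in enumerate(self.nodes)}

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edge_list)

    def node_index(self, gene: str) -> int:
        return self._node_index[gene]

    def signs(self):
        import numpy as np

        return np.array(
            [self.graph.edges[e]["sign"] for e in self.edge_list], dtype=float
        )

    def weights(self):
        import numpy as np

        return np.array(
            [self.graph.edges[e]["weight"] for e in self.edge_list], dtype=float
        )

    def has_nodes(self, genes) -> bool:
        return all(g in self._node_index for g in genes)

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self) -> str:
        lines = ["source\ttarget\tsign\tweight"]
        for u, v in self.edge_list:
            d = self.graph.edges[u, v]
            lines.append(f"{u}\t{v}\t{d['sign']:d}\t{d['weight']!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, text: str) -> "Network":
        g = nx.DiGraph()
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if not lines or lines[0].split("\t")[:2] != ["source", "target"]:
            raise DefinitionError("network TSV must start with a source/target header")
        for ln in lines[1:]:
            u, v, s, w = ln.split("\t")
            g.add_edge(u, v, sign=int(s), weight=float(w))
        return cls(g)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def parse_drug_table(table_text: str) -> list[DrugDefinition]:
    """Parse a tab-separated drug-target table into one drug per column.

    Layout: ``gene<TAB>protein_name<TAB>effect<TAB><drug1><TAB><drug2>...``.
    A row belongs to a drug's target set iff that drug's cell holds a
    literature reference; a bare ``-`` excludes the row for that drug.

    Raises :class:`DefinitionError` on a non-+/-1 effect, a gene listed twice
    for one drug, or a table yielding a drug with no targets.
    """
    lines = [ln for ln in table_text.splitlines() if ln.strip()]
    if len(lines) < 2:
        raise DefinitionError("drug table has no target rows")
    header = lines[0].split("\t")
    if header[:3] != ["gene", "protein_name", "effect"]:
        raise DefinitionError("drug table must start with gene/protein_name/effect")
    drug_names = header[3:]
    if not drug_names:
        raise DefinitionError("drug table has no drug columns")
    per_drug: dict[str, list[Target]] = {d: [] for d in drug_names}
    for ln in lines[1:]:
        cells = ln.split("\t")
        if len(cells) != len(header):
            raise DefinitionError(f"malformed row: {ln!r}")
        gene, pname, eff_s = cells[0], cells[1], cells[2]
        try:
            effect = int(eff_s)
        except ValueError:
            raise DefinitionError(f"non-integer effect {eff_s!r} for {gene}") from None
        protein = ProteinRef(gene, pname)
        for drug, cell in zip(drug_names, cells[3:]):
            if cell.strip() in ("", "-"):
                continue
            if gene in (t.protein.gene_symbol for t in per_drug[drug]):
                raise DefinitionError(f"duplicate gene {gene} for drug {drug}")
            per_drug[drug].append(Target(protein, effect))
    return [DrugDefinition(d, per_drug[d]) for d in drug_names]


def write_drug_table(drugs: list[DrugDefinition]) -> str:
    """Inverse of :func:`parse_drug_table` (reference cells become ``x``)."""
    genes: dict[str, tuple[str, int]] = {}
    for d in drugs:
        for t in d.targets:
            genes[t.protein.gene_symbol] = (t.protein.display_name, t.effect)
    out = io.StringIO()
    out.write("gene\tprotein_name\teffect\t" + "\t".join(d.name for d in drugs) + "\n")
    for g, (pname, eff) in genes.items():
        cells = []
        for d in drugs:
            cells.append("x" if g in d.target_genes else "-")
        out.write(f"{g}\t{pname}\t{eff}\t" + "\t".join(cells) + "\n")
    return out.getvalue()


def parse_disease_definition(text: str, n_motives: int = 4) -> DiseaseDefinition:
    """Parse a YAML disease definition with signed motive blocks.

    Expected structure::

        name: ADHD
        motives:
          neurotransmitter imbalance: {GENE1: 1, GENE2: -1}
          ...

    The definition must carry exactly ``n_motives`` motive blocks (4 for the
    default disease), each nonempty, with signs restricted to +/-1.
    """
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "motives" not in doc:
        raise DefinitionError("disease definition must have a 'motives' mapping")
    motive_map = doc["motives"]
    if len(motive_map) != n_motives:
        raise DefinitionError(
            f"expected {n_motives} motives, found {len(motive_map)}"
        )
    motives = []
    for mname, members in motive_map.items():
        if not members:
            raise DefinitionError(f"motive {mname!r} is empty")
        entries = []
        for gene, sign in members.items():
            if sign not in (-1, 1):
                raise DefinitionError(
                    f"unknown sign token {sign!r} for {gene} in motive {mname!r}"
                )
            entries.append((ProteinRef(str(gene)), int(sign)))
        motives.append(Motive(str(mname), entries))
    return DiseaseDefinition(str(doc.get("name", "disease")), motives)


def write_disease_definition(disease: DiseaseDefinition) -> str:
    doc = {
        "name": disease.name,
        "motives": {
            m.name: {p.gene_symbol: s for p, s in m.members} for m in disease.motives
        },
    }
    return yaml.safe_dump(doc, sort_keys=False)


def combine_treatments(
    primary: DrugDefinition, co_drug: DrugDefinition
) -> DrugDefinition:
    """Merge a primary drug with a co-treatment into one target set.

    Proteins targeted by both drugs with the same sign appear once; opposite
    signs are both retained and conflict-flagged — the net stimulus at such a
    protein is 0 under the signed-intensity summation rule applied at
    stimulus-construction time. Commutative and associative up to ordering.
    """
    merged: dict[tuple[str, int], Target] = {}
    for t in list(primary.targets) + list(co_drug.targets):
        key = (t.protein.gene_symbol, t.effect)
        if key not in merged:
            merged[key] = t
    by_gene: dict[str, list[Target]] = {}
    for (g, _), t in merged.items():
        by_gene.setdefault(g, []).append(t)
    targets = []
    for g in sorted(by_gene):
        entries = by_gene[g]
        conflict = len(entries) > 1
        for t in sorted(entries, key=lambda t: t.effect):
            targets.append(replace(t, conflict=conflict))
    return DrugDefinition(
        name=f"{primary.name}+{co_drug.name}",
        targets=targets,
        pk_ref=primary.pk_ref,
    )


# ---------------------------------------------------------------------------
# shipped fixtures
# ---------------------------------------------------------------------------

def _data_text(relpath: str) -> str:
    return (resources.files("virtrial") / "data" / relpath).read_text()


def load_study_drugs() -> dict[str, DrugDefinition]:
    """The two study drugs parsed from the shipped target table.

    Returns ``{"vLDX": ..., "vMPH": ...}`` with PK handles wired to the
    Elvanse and Medikinet parameter fixtures.
    """
    drugs = parse_drug_table(_data_text("drug_targets.tsv"))
    pk_map = {"vLDX": "elvanse", "vMPH": "medikinet"}
    out = {}
    for d in drugs:
        d.pk_ref = pk_map.get(d.name, "")
        out[d.name] = d
    return out


def load_profile_catalog() -> list[dict]:
    """Names and co-treatment lists of the study's comorbidity profiles."""
    doc = yaml.safe_load(_data_text("comorbidity_profiles.yaml"))
    return doc["profiles"]
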