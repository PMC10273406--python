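"""Signed-network signal-propagation engine.

The engine realizes the published contract of ensemble network modelling:
a stimulus (signed per-protein intensities in [-1,1]) enters a directed
signed weighted network and is propagated to bounded protein activities in
(-1,1); an ensemble of "mathematical solutions" — alternative edge-weight
assignments trained to satisfy drug-response restrictions above an accuracy
threshold — captures biological variability, and every downstream statistic
treats solutions as the unit of replication.

Propagation is a saturating linear recursion:

    x_0 = 0,   x_{t+1}(v) = tanh( sum_{u->v} sign(u,v) w(u,v) x_t(u) + s(v) )

run for a fixed number of steps (network diameter + 2 by default, enough
for signal to traverse the graph). Training is multiplicative-perturbation
hill climbing on a hinge loss measuring how far each restriction's
sign-adjusted disease tSignal sits outside its required band; a candidate is
retained iff its final accuracy (fraction of restrictions satisfied)
strictly exceeds the threshold (0.85 per the study's filter).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .definitions import ComorbidityProfile, Network
from .synthetic import Restriction

DEFAULT_ACCURACY_MIN = 0.85
#: Baseline intensity at which a comorbidity's molecular definition is
#: applied as part of a patient's stimulus.
BASELINE_COMORBIDITY_INTENSITY = 0.5


class QSPError(ValueError):
    pass


@dataclass
class MathematicalSolution:
    """One trained edge-weight assignment (aligned to ``network.edge_list``)."""

    weights: np.ndarray
    accuracy: float
    seed: int

    def __post_init__(self):
        if not np.all(np.isfinite(self.weights)):
            raise QSPError("solution weights must be finite")


@dataclass
class SolutionEnsemble:
    """Ensemble of restriction-satisfying solutions for one network."""

    solutions: list[MathematicalSolution]
    accuracy_min: float = DEFAULT_ACCURACY_MIN
    patient_id: str = ""
    drug_name: str = ""

    def __post_init__(self):
        if not self.solutions:
            raise QSPError("ensemble is empty after filtering")
        bad = [s.accuracy for s in self.solutions if not s.accuracy > self.accuracy_min]
        if bad:
            raise QSPError(
                f"ensemble contains solutions at accuracy {bad} <= "
                f"{self.accuracy_min}"
            )

    def __len__(self) -> int:
        return len(self.solutions)


def default_steps(network: Network) -> int:
    """Propagation depth: undirected diameter + 2."""
    und = network.graph.to_undirected()
    return nx.diameter(und) + 2


def _adjacency(network: Network, weights: np.ndarray) -> np.ndarray:
    """Signed weighted adjacency, A[u, v] = sign * weight for edge u->v."""
    n = network.n_nodes
    a = np.zeros((n, n))
    signs = network.signs()
    for k, (u, vtx) in enumerate(network.edge_list):
        a[network.node_index(u), network.node_index(vtx)] = signs[k] * weights[k]
    return a


def _stimulus_vector(network: Network, stimulus: dict[str, float]) -> np.ndarray:
    s = np.zeros(network.n_nodes)
    for gene, val in stimulus.items():
        if gene not in network._node_index:
            raise QSPError(f"stimulus protein {gene} is not a network node")
        s[network.node_index(gene)] = val
    return s


def propagate(
    solution: MathematicalSolution,
    network: Network,
    stimulus: dict[str, float],
    steps: int | None = None,
) -> dict[str, float]:
    """Propagate a stimulus to per-protein activities in (-1, 1).

    Runs the tanh recursion for ``steps`` iterations from the zero state and
    returns the final activity of every node.
    """
    if steps is None:
        steps = default_steps(network)
    if steps < 1:
        raise QSPError("steps must be >= 1")
    # cache the signed adjacency on the solution; weights are fixed per
    # solution so the cache only invalidates when the network changes
    cached = getattr(solution, "_adj_cache", None)
    if cached is not None and cached[0] is network:
        a = cached[1]
    else:
        a = _adjacency(network, solution.weights)
        solution._adj_cache = (network, a)
    s = _stimulus_vector(network, stimulus)
    x = np.zeros(network.n_nodes)
    for _ in range(steps):
        x = np.tanh(x @ a + s)
        if not np.all(np.isfinite(x)):
            raise QSPError("non-finite activity during propagation")
    return {node: float(x[i]) for i, node in enumerate(network.nodes)}


def _signed_tsignal(activity: dict[str, float], response: list[tuple[str, int]]):
    """Sign-adjusted mean activity over a signed response set."""
    vals = [-sign * activity[gene] for gene, sign in response]
    return float(np.mean(vals))


def solution_accuracy(
    solution: MathematicalSolution,
    network: Network,
    restrictions: list[Restriction],
    steps: int | None = None,
) -> float:
    """Fraction of restrictions whose propagated sign-adjusted tSignal falls
    inside the required band."""
    if not restrictions:
        raise QSPError("at least one restriction required")
    if steps is None:
        steps = default_steps(network)
    ok = 0
    for r in restrictions:
        act = propagate(solution, network, r.stimulus, steps)
        t = _signed_tsignal(act, r.response)
        if r.band[0] <= t <= r.band[1]:
            ok += 1
    return ok / len(restrictions)


def _restriction_loss(
    weights: np.ndarray,
    network: Network,
    restrictions: list[Restriction],
    steps: int,
) -> float:
    """Hinge distance of each restriction's tSignal from its band, summed."""
    sol = MathematicalSolution(weights, accuracy=1.0, seed=-1)
    loss = 0.0
    for r in restrictions:
        act = propagate(sol, network, r.stimulus, steps)
        t = _signed_tsignal(act, r.response)
        lo, hi = r.band
        loss += max(0.0, lo - t, t - hi)
    return loss


def train_ensemble(
    network: Network,
    restrictions: list[Restriction],
    n_solutions: int,
    accuracy_min: float = DEFAULT_ACCURACY_MIN,
    seed: int = 0,
    iterations: int = 500,
    retry_factor: int = 10,
    steps: int | None = None,
) -> SolutionEnsemble:
    """Train an ensemble of restriction-satisfying weight assignments.

    Each candidate starts from the network's weights jittered by a lognormal
    factor and hill-climbs for ``iterations`` proposals (multiplicative
    perturbation of a random 10% edge subset, accepted when the hinge loss
    does not increase, early-stopped at zero loss). Candidates whose final
    accuracy strictly exceeds ``accuracy_min`` are retained, until
    ``n_solutions`` are collected or ``retry_factor * n_solutions``
    candidates have been tried. Deterministic per seed.
    """
    if n_solutions < 1:
        raise QSPError("n_solutions must be >= 1")
    if not restrictions:
        raise QSPError("restrictions must be nonempty")
    if steps is None:
        steps = default_steps(network)
    base = network.weights()
    m = len(base)
    rng = np.random.default_rng(seed)
    retained: list[MathematicalSolution] = []
    budget = retry_factor * n_solutions
    for cand in range(budget):
        cand_rng = np.random.default_rng(rng.integers(2**31))
        w = base * cand_rng.lognormal(0.0, 0.5, size=m)
        loss = _restriction_loss(w, network, restrictions, steps)
        for _ in range(iterations):
            if loss == 0.0:
                break
            k = max(1, m // 10)
            pick = cand_rng.choice(m, size=k, replace=False)
            w_new = w.copy()
            w_new[pick] *= cand_rng.lognormal(0.0, 0.2, size=k)
            new_loss = _restriction_loss(w_new, network, restrictions, steps)
            if new_loss <= loss:
                w, loss = w_new, new_loss
        acc = solution_accuracy(
            MathematicalSolution(w, 0.0, cand), network, restrictions, steps
        )
        if acc > accuracy_min:
            retained.append(MathematicalSolution(w, acc, cand))
            if len(retained) == n_solutions:
                break
    if not retained:
        raise QSPError(
            f"restrictions unsatisfiable at accuracy_min={accuracy_min} "
            f"within {budget} candidates"
        )
    return SolutionEnsemble(retained, accuracy_min)


def build_stimulus(
    modulation: dict[str, float],
    profile: ComorbidityProfile | None = None,
    baseline_intensity: float = BASELINE_COMORBIDITY_INTENSITY,
) -> dict[str, float]:
    """Patient stimulus: drug modulation plus the comorbidity's molecular
    definition at baseline intensity, summed per protein and clipped to
    [-1, 1]."""
    stim = dict(modulation)
    if profile is not None:
        for protein, sign in profile.molecular_definition:
            g = protein.gene_symbol
            stim[g] = stim.get(g, 0.0) + sign * baseline_intensity
    return {g: float(np.clip(v, -1.0, 1.0)) for g, v in stim.items()}


def patient_drug_model(
    network: Network,
    modulation: dict[str, float],
    ensemble: SolutionEnsemble,
    profile: ComorbidityProfile | None = None,
    steps: int | None = None,
    baseline_intensity: float = BASELINE_COMORBIDITY_INTENSITY,
) -> list[dict[str, float]]:
    """One ActivityVector per ensemble solution for a patient-drug pair.

    The stimulus combines the patient's PK-derived target modulation with
    the comorbidity profile's molecular definition (signed-intensity
    summation, clipped). Raises if the modulation references a protein
    absent from the network.
    """
    missing = [g for g in modulation if g not in network._node_index]
    if missing:
        raise QSPError(f"modulation references non-network proteins: {missing}")
    if steps is None:
        steps = default_steps(network)
    stim = build_stimulus(modulation, profile, baseline_intensity)
    return [propagate(sol, network, stim, steps) for sol in ensemble.solutions]
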