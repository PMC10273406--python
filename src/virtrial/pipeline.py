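"""End-to-end in silico trial orchestration.

Wires the whole engine together on synthetic inputs: build the network and
disease embedding, sample a virtual cohort, simulate per-patient drug
exposure with the PBPK model, train the solution ensemble against
drug-efficacy restrictions, propagate patient-specific stimuli, and run the
outcome statistics (tSignal table, reverted-protein taxonomy, demographic
correlations).

The config's cohort and ensemble sizes default to a desk-scale study that
runs in seconds; the full study quotas live in
:class:`virtrial.population.CohortSpec.study_default`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import qsp
from .definitions import DrugDefinition, load_study_drugs
from .moa import RevertedProteinReport, reverted_protein_report, tsignal
from .pbpk import (
    build_patient_params,
    load_pk_parameters,
    modulation_from_curve,
    simulate_pbpk,
)
from .population import CohortSpec, VirtualPatient, cohort_to_frame, sample_cohort
from .synthetic import (
    generate_comorbidity_profiles,
    generate_disease_embedding,
    generate_network,
    generate_reference_demographics,
    generate_restrictions,
)


@dataclass
class StudyConfig:
    """Desk-scale defaults for an end-to-end synthetic trial."""

    n_proteins: int = 40
    edge_density: float = 0.08
    motive_sizes: tuple[int, int, int, int] = (4, 4, 4, 4)
    cohort_spec: CohortSpec = field(
        default_factory=lambda: CohortSpec(
            total_size=72,
            profile_quotas={"depression": 4, "tics": 4},
            main_group_minimum=8,
            population="adult",
        )
    )
    n_solutions: int = 4
    training_iterations: int = 200
    #: training drugs and their scaled clinical efficacies
    training_efficacies: dict[str, float] = field(
        default_factory=lambda: {"vLDX": 0.6, "vMPH": 0.45}
    )
    pk_subsample: int = 12  # patients receiving a full per-patient PBPK run


@dataclass
class StudyResult:
    network: object
    disease: object
    drugs: dict[str, DrugDefinition]
    profiles: dict[str, object]
    cohort: list[VirtualPatient]
    ensemble: qsp.SolutionEnsemble
    modulations: dict[str, dict[str, dict[str, float]]]  # drug -> patient -> mod
    tsignals: pd.DataFrame  # patient rows x drug tSignal columns + demographics
    solution_activities: dict[str, list[dict[str, float]]]  # drug -> per-solution
    reverted: RevertedProteinReport


def patient_tsignal(
    network, disease, modulation, ensemble, profile=None, steps=None
) -> float:
    """Mean tSignal over ensemble solutions for one patient-drug stimulus."""
    acts = qsp.patient_drug_model(network, modulation, ensemble, profile, steps)
    return float(np.mean([tsignal(a, disease).value for a in acts]))


def run_study(config: StudyConfig | None = None, seed: int = 0) -> StudyResult:
    """Run the full synthetic trial and collect its analysis substrate."""
    cfg = config or StudyConfig()
    drugs = load_study_drugs()
    target_genes = sorted({g for d in drugs.values() for g in d.target_genes})
    network = generate_network(
        cfg.n_proteins, cfg.edge_density, seed, include=target_genes
    )
    disease = generate_disease_embedding(network, cfg.motive_sizes, seed + 1)
    profiles = generate_comorbidity_profiles(network, seed + 2)
    reference = generate_reference_demographics()
    cohort = sample_cohort(reference, cfg.cohort_spec, seed + 3)
    restrictions = generate_restrictions(
        network,
        disease,
        [(drugs[name], eff) for name, eff in cfg.training_efficacies.items()],
    )
    ensemble = qsp.train_ensemble(
        network,
        restrictions,
        cfg.n_solutions,
        seed=seed + 4,
        iterations=cfg.training_iterations,
    )
    steps = qsp.default_steps(network)

    # per-patient exposure -> modulation -> tSignal (PBPK on a subsample,
    # nearest-weight reuse beyond it keeps the ODE count bounded)
    pk_patients = cohort[: cfg.pk_subsample]
    modulations: dict[str, dict[str, dict[str, float]]] = {}
    rows = []
    for name, drug in drugs.items():
        pk = load_pk_parameters(drug.pk_ref)
        per_patient: dict[str, dict[str, float]] = {}
        curves = {}
        for patient in pk_patients:
            params = build_patient_params(patient, pk)
            curve = simulate_pbpk(params, pk)
            curves[patient.id] = curve
            per_patient[patient.id] = modulation_from_curve(curve, drug, pk.ec50)
        weights = np.array([p.weight for p in pk_patients])
        for patient in cohort[cfg.pk_subsample:]:
            nearest = pk_patients[int(np.argmin(np.abs(weights - patient.weight)))]
            per_patient[patient.id] = per_patient[nearest.id]
        modulations[name] = per_patient
    for patient in cohort:
        row = dict(id=patient.id)
        for name in drugs:
            profile = profiles[patient.profile]
            ts = patient_tsignal(
                network, disease, modulations[name][patient.id],
                ensemble, profile, steps,
            )
            base = patient_tsignal(
                network, disease, {}, ensemble, profile, steps,
            ) if profile.molecular_definition else 0.0
            row[f"tsignal_{name}"] = ts
            row[f"baseline_{name}"] = base
        rows.append(row)
    tsig = cohort_to_frame(cohort).merge(pd.DataFrame(rows), on="id")

    # per-solution mean activities pooled over the main-group PK patients
    # (solutions are the statistical unit for the drug-drug comparison)
    solution_activities: dict[str, list[dict[str, float]]] = {}
    for name, drug in drugs.items():
        per_solution: list[dict[str, float]] = []
        for sol in ensemble.solutions:
            acc = None
            for patient in pk_patients:
                stim = qsp.build_stimulus(modulations[name][patient.id])
                act = qsp.propagate(sol, network, stim, steps)
                if acc is None:
                    acc = {g: v for g, v in act.items()}
                else:
                    for g, v in act.items():
                        acc[g] += v
            per_solution.append({g: v / len(pk_patients) for g, v in acc.items()})
        solution_activities[name] = per_solution
    names = list(drugs)
    reverted = reverted_protein_report(
        solution_activities[names[0]], solution_activities[names[1]], disease
    )
    return StudyResult(
        network=network,
        disease=disease,
        drugs=drugs,
        profiles=profiles,
        cohort=cohort,
        ensemble=ensemble,
        modulations=modulations,
        tsignals=tsig,
        solution_activities=solution_activities,
        reverted=reverted,
    )
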