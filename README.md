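# virtrial

An in silico clinical trial (ISCT) engine for comparing the mechanisms of
action of CNS stimulants — virtual lisdexamfetamine (vLDX) and virtual
methylphenidate (vMPH) — in virtual attention-deficit/hyperactivity disorder
(ADHD) populations.

The package is aimed at quantitative-systems-pharmacology practitioners who
want a fully offline, reproducible implementation of the ISCT workflow:
every input that a production study would draw from proprietary or external
sources (the protein network, curated disease protein sets, reference
demographics, a drug database) is emulated by a first-class synthetic-data
module with controllable statistical structure, so the entire pipeline is
testable on a laptop.

## What it computes

**Virtual populations.** Randomized cohorts of virtual patients (age, sex,
weight, height, BMI, comorbidity profile) are sampled against reference
demographic distributions under the study quotas: populations of 1,300
patients, at least 100 per comorbidity profile, at least 500 in the main
comorbidity-free group, a hard floor of 71 patients per cohort (the minimum
size at which case/control expression data separate with 95% power), and a
5% relative tolerance on every summary statistic.

**Exposure.** A 14-compartment flow-limited whole-body PBPK model (gut
lumen, gut tissue, liver, kidney, brain, heart, lung, spleen, muscle,
adipose, skin, bone, arterial and venous blood) turns each patient's
morphometrics into a drug concentration curve. Oral bioavailability F is
applied to the gut→liver absorption flux, so the realized oral/IV AUC ratio
reproduces the published values (96.4% Elvanse, 30% Medikinet, 32%
Concerta). Brain exposure is summarized into signed per-target modulation
intensities via mean receptor occupancy C/(C+EC50).

**Network response.** A signed directed protein network propagates each
patient-drug stimulus to bounded protein activities

    x₀ = 0,  x_{t+1}(v) = tanh( Σ_{u→v} sign·w·x_t(u) + s(v) )

through ensembles of "mathematical solutions": alternative edge-weight
assignments trained to satisfy restrictions pairing known drug stimuli with
required disease-response bands, with solutions retained only above 85%
restriction accuracy.

**Outcomes.** The efficacy proxy is the tSignal — the sign-adjusted mean
predicted activity over the disease protein set (positive = reversion of
the disease signature), with per-motive breakdowns over the four ADHD
pathophysiology motives (neurotransmitter imbalance, neuroinflammation,
circadian system imbalance, altered neural viability). On top of it sit the
reverted-protein taxonomy (reverted ⊇ differentially reverted ⊇ most
strongly reverted), hypergeometric enrichment, one-at-a-time target
sensitivity sweeps and random target-set extension robustness, demographic
correlations with categorical strength labels, Jarque-Bera-gated group
tests, and co-treatment impact versus a random drug pool — all under
Benjamini-Hochberg FDR control.

## Worked example

Realized oral bioavailability of the Elvanse-parameterized vLDX model for a
70 kg reference adult:

```sh
$ virtrial pbpk --drug elvanse --bioavailability
realized bioavailability for elvanse: 96.4%
```

The number is the AUC ratio of a simulated oral dose to an equal
intravenous bolus in venous blood — i.e. the model *realizes* the
bioavailability it was parameterized with, rather than asserting it.

A desk-scale end-to-end trial (72 patients, 4 trained solutions):

```sh
$ virtrial trial --seed 1
{
  "patients": 72,
  "solutions": 4,
  "min_solution_accuracy": 1.0,
  "mean_tsignal_vLDX": 0.06693689798909051,
  "mean_tsignal_vMPH": 0.08696328760816924,
  "reverted_vLDX": ["G008", "G014", "G021", "MAOA", "SLC6A2"],
  "reverted_vMPH": ["G008", "G021", "G032", "MAOA", "SLC6A2"],
  "most_strongly_reverted": []
}
```

Every solution in the ensemble satisfied all training restrictions
(accuracy 1.0 > the 0.85 filter). The mean tSignals are the cohort-average
efficacy proxies of the two virtual drugs on this synthetic network; the
reverted lists name disease proteins whose activity each drug pushed beyond
0.5 against their disease activation sign (symbols like `G008` are
synthetic network nodes; `MAOA`, `SLC6A2` are drug-target genes embedded in
the network). On this small fixture no protein separated the two drugs'
solution ensembles perfectly, so the most-strongly-reverted set is empty.

The same machinery is available as a library; see `virtrial.pipeline.run_study`
for the orchestration entry point and the module docstrings for the
individual stages.

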