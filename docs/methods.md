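# Methods

This note documents the models implemented in `virtrial`, the assumptions
behind them, the parameters that matter, and the limits of what the
synthetic-data fixtures can demonstrate.

## Study structure

The engine reproduces the structure of an in silico clinical trial for ADHD
stimulants: molecular definitions of drugs and disease, randomized virtual
populations, per-patient pharmacokinetics, network-propagation response
models, and a battery of comparative statistics. The production studies this
workflow mirrors rely on a proprietary curated protein network, curated
disease protein sets, clinical-trial demographic tables, and a commercial
drug database. None of those are redistributable, so the package generates
statistical stand-ins for each (see *Synthetic data* below); the numeric
design constants of the trial itself — population sizes and quotas, the
power floor, tolerance, accuracy filter, subsample fraction, sweep and
robustness grids, correlation bands — are implemented exactly.

## Drug and disease definitions

A drug is a signed protein-target set (+1 activation, −1 inhibition) plus a
pharmacokinetic parameter record. The shipped target table defines vLDX
(7 targets: TAAR1 +1; SLC18A2, SLC6A3, SLC6A2, SLC6A4, MAOA, MAOB −1) and
vMPH (3 targets: SLC6A3 −1, SLC6A2 −1, HTR1A +1); membership of a table row
in a drug's set is decided by the presence of a literature-reference cell
for that drug.

The disease is four named motives — neurotransmitter imbalance,
neuroinflammation, circadian system imbalance, altered neural viability —
each a set of proteins with disease activation signs.

Co-treatments are merged by target-set union. When the two drugs carry
opposite signs on the same protein, both entries are retained and
conflict-flagged; the ambiguity is resolved only at stimulus-construction
time by summing signed intensities (and clipping to [−1, 1]), which makes
the merge commutative/associative and preserves antagonism (full-intensity
+1 and −1 cancel to a net stimulus of 0).

## Virtual populations

Patients carry age, sex, weight, height (BMI derived exactly), an age block
(children 6–12, adolescents 13–17, adults 18–65), and a comorbidity profile
(one of eight study profiles or "none"). Sampling is simple and auditable:
uniform ages within the block, Bernoulli sex, and 3-σ-truncated normal
height/weight around block-specific growth trends. A sampled cohort is
accepted only if every per-block summary statistic (mean age, height,
weight, BMI; female proportion) lies within the tolerance (default 5%
relative — the study's inclusion/exclusion tolerance, interpreted as
relative deviation because that choice is scale-free) of its reference
expectation; otherwise the whole cohort is resampled, up to 50 attempts.
Quota satisfaction (total size, per-profile minima, main-group minimum) is a
hard postcondition, never best-effort.

The 71-patient floor is a study constant: the minimum per-cohort size at
which pooled case/control expression scores separate at 95% power. The
package also implements the computation that produces such a floor:
the per-sample mean over disease genes is reduced to a pooled standardized
effect size d, and the smallest per-group n with two-sample two-sided
t-test power ≥ 95% at α = 0.05 is found by integer search over the
noncentral-t power function. The statistic behind the original power
analysis is not public; the pooled-score t test was chosen because it is
the simplest statistic consistent with the stated design, and it is checked
against the closed-form solver in `statsmodels` (±10%) in the tests.

## PBPK model

A flow-limited 14-compartment whole-body model. The compartment list (gut
lumen, gut tissue, liver, kidney, brain, heart, lung, spleen, muscle,
adipose, skin, bone, arterial blood, venous blood) is the canonical
whole-body topology adopted for a model described only by its compartment
count. Structure:

- Oral doses enter the gut lumen; absorption transfers `F · ka · A_lumen`
  into the liver, with the remaining fraction (1 − F) discarded as
  unabsorbed/first-pass loss. Lumping incomplete absorption and hepatic
  extraction into the single oral bioavailability F guarantees that the
  realized oral/IV venous AUC ratio equals the configured F for any
  parameter set — the model realizes its own headline parameter instead of
  being fitted to it.
- Gut tissue and spleen drain through the liver (portal flow); all other
  tissues exchange with arterial blood at their perfusion rate with
  tissue:plasma partition coefficients; lung sits between venous and
  arterial blood at cardiac output.
- Elimination is renal only (clearance acting on the kidney's emergent
  venous concentration), matching a kidney-as-main-clearance-organ design;
  hepatic loss is folded into F.

Patient individualization is allometric: volumes ∝ W/70 kg, flows and
clearance ∝ (W/70)^0.75, with uniform sex multipliers (female 0.92) so the
flows-sum-to-cardiac-output invariant survives scaling. Age multipliers are
present in the physiology table but set to 1.0 by default: weight scaling
already carries most of the pediatric difference at this level of detail.

Numerics: LSODA, rtol 1e-8 / atol 1e-10, fixed 0.1 h output grid. The
venous AUC is accumulated as an extra ODE state rather than by trapezoid on
the output grid — the IV bolus decays from the venous pool with a ~0.01 h
time constant, which an output-grid quadrature cannot resolve.
Bioavailability simulations run single doses over 15 elimination half-lives
(half-life estimated as ln2 · Vss/CL); mass balance holds to <1e-4 relative
and dose→AUC linearity to ~1e-6.

The drug parameter fixtures carry the published oral bioavailabilities
(Elvanse 96.4%, Medikinet 30%, Concerta 32%) together with
literature-informed amphetamine/methylphenidate-like absorption rates,
renal clearances and partition coefficients; the partition and EC50 values
are plausible round numbers, not fitted to concentration data. Target
modulation uses the brain as effect site (CNS drugs; configurable) and
summarizes exposure as the mean occupancy C/(C+EC50) over the final dosing
day — an average rather than Cmax, because averages are stable across
regimens.

## Network engine

The response model honours the published contract of ensemble network
modelling: a stimulus in [−1, 1] per protein enters the network and yields
bounded protein activities; an ensemble of restriction-trained weight
assignments ("mathematical solutions") represents biological variability.
The proprietary internals of the original technology are not public; this
engine is the package's own documented realization of that contract, and
every downstream statistic depends only on the contract.

Propagation is the saturating recursion `x_{t+1} = tanh(Aᵀx_t + s)` run for
(undirected network diameter + 2) steps — enough for signal to traverse the
graph; the step count is configurable. Training restrictions pair a known
drug's full-intensity signed target set with a required band on the
sign-adjusted disease tSignal, centred at the drug's clinical efficacy
mapped through a scale factor (default 0.3, the tSignal magnitude regime
reachable on the synthetic substrate) with half-width 0.15 (a band makes
"accuracy = fraction of restrictions satisfied" well defined; the original
restriction form is unpublished). Candidates start from lognormally
jittered network weights and hill-climb (multiplicative perturbation of a
random 10% edge subset, 500 proposals by default, early stop at zero hinge
loss); a candidate is retained iff its accuracy is strictly greater than
0.85. The printed phrase describing the filter is self-contradictory
("low accuracy (>85%)... excluded"); the strictly-greater retention reading
is used. Solutions are shared across patients, with patient specificity
entering through the stimulus (PK-derived modulation plus the comorbidity
profile's molecular definition at baseline intensity 0.5, summed and
clipped) — whether the original work trained per-patient solutions is not
specified; shared solutions keep the statistics interpretable with
solutions as the replication unit.

## Outcome statistics

- **tSignal** = mean over the disease set of (−disease_sign · activity), so
  positive values mean reversion of the disease signature. Whether the
  original summary is sign-adjusted or raw cannot be determined from the
  published description; the sign-adjusted convention is isolated in one
  function and documented here.
- **Reverted protein**: |mean activity| strictly > 0.5 and direction
  opposite the disease sign (the reversion phrase is read directionally).
- **Differentially reverted**: two-sided Wilcoxon rank-sum across the two
  drugs' per-solution activities (exact for group sizes ≤ 8 without ties,
  normal approximation with tie correction otherwise), BH FDR across the
  reverted-by-either candidates, retained at FDR < 0.05. All-tied proteins
  are reported with FDR 1, not dropped.
- **Most strongly reverted**: a single activity threshold separates the two
  drugs' solutions with 100% accuracy, i.e. their value ranges are
  disjoint. The nesting most_strongly ⊆ differentially ⊆ reverted-by-either
  is asserted on every report construction.
- **Enrichment**: hypergeometric upper tail within an explicit universe,
  BH-corrected; annotation terms come from GMT files.
- **Sensitivity**: the derivative of tSignal with respect to a single
  target intensity is realized as the finite-difference grid actually
  computed in such analyses — one target at a time scaled to
  {0, 25, 50, 75, 100}% of its drug effect, reported as a percentage of the
  unmodified model's solution-averaged tSignal. Robustness extends the
  target set with j = 1..20 random non-target proteins at full intensity
  and random sign, 50 fresh draws per j (fresh, not nested — the
  alternative is unspecified). Both use a 5% random subsample of the
  solution pool, size round-half-up with floor 1 (reproducing 1,250 from
  25,000).
- **Cohort effects**: Pearson correlations labelled Strong (|ρ| ≥ 0.8),
  Moderate ([0.5, 0.8)), Low ([0.3, 0.5)), Negligible (< 0.3), overridden
  to NotSignificant at FDR ≥ 0.05. "Isolating" one covariate from another
  is implemented as quantile-stratified correlation (default 3 strata),
  mirroring the low-BMI/low-age phrasing of such analyses, rather than
  partial correlation. Group comparisons gate on Jarque-Bera normality at
  α = 0.05 per group (t test iff both pass, Wilcoxon otherwise) and carry
  significance bands ns / <0.05 / <0.001. Co-treatment impact reports both
  the direct two-group p and an empirical pool p — the (r+1)/(n+1)
  add-one-smoothed fraction of random pool drugs whose |mean tSignal
  shift| meets the observed one; smoothing avoids p = 0. BH families are
  defined per analysis table.

## Synthetic data: what it emulates and what it does not

- **Network**: directed Erdős–Rényi with Rademacher signs and |N(0,1)|
  weights, redrawn until weakly connected — the simplest connected signed
  substrate. It has no hub structure, modularity, or curated biology; tests
  passing on it demonstrate the correctness of the pipeline's mechanics,
  not any biological claim about real drugs.
- **Disease embedding**: four disjoint motives sampled uniformly with
  random signs; real disease sets overlap pathways and are not sign-random.
- **Expression**: Gaussian mean shift on disease genes only, making the
  power computation analytically checkable; no covariance, batch effects,
  or count noise.
- **Demographics**: uniform ages with linear growth trends and truncated
  normal morphometrics; real reference-trial tables are not reproduced.
- **Drug pool**: uniform random target sets of uniform random size — a
  stand-in for a drug database's target-size distribution, not its
  pharmacology.
- **Comorbidity profiles**: the eight study profile names and typical
  co-treatment drug lists are shipped; their molecular definitions are
  random signed protein sets because the real ones are not public.

Consequently the headline biological outputs of the production studies
(absolute tSignal levels per drug and cohort, specific correlation values,
named enriched processes) are out of reach by design; what the package
reproduces exactly is every number the trial design itself controls, and
qualitative behaviours (e.g. random target-set extension degrading the
percent tSignal) are asserted on its own fixtures.

## Problem sizes

The test suite and the worked examples run desk-scale configurations chosen
as the smallest sizes at which each property is meaningful: 40-protein
networks (with the 8 real target genes embedded), 4×4-member motives,
cohorts of 71–200 patients for behavioural tests and one full 1,300-patient
study-quota cohort, ensembles of 3–5 solutions, 10–15 extension sets for
trend checks (the full 50×20 design is exercised once for shape), 10-patient
PBPK conservation sweeps, and 100–200 replicate calibration loops.

## Known limitations

- The PBPK model is flow-limited with a single lumped F; prodrug conversion
  kinetics (lisdexamfetamine → d-amphetamine) are not modelled as a
  separate species, and partition coefficients are not fitted to clinical
  concentration data.
- Hill-climb training finds restriction-satisfying solutions but does not
  characterize the solution space the way a dedicated sampler would;
  ensemble diversity comes only from random initialization.
- Quantile-stratified correlation controls a covariate coarsely; a partial
  correlation option would be a natural extension.
- The cohort sampler resamples whole cohorts to meet the tolerance; for
  very tight tolerances or tiny cohorts the 50-attempt budget can fail, by
  design, with the offending variable named.
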