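# Oral PK parameters for virtual lisdexamfetamine (Elvanse), the vLDX drug.
# Bioavailability is the published oral F; the remaining parameters are
# literature-informed amphetamine-like values (renal clearance for a 70 kg
# reference adult; tissue:plasma partition coefficients typical of a basic,
# moderately lipophilic CNS stimulant). EC50 is a single effect-site potency
# applied to every protein target.
name: elvanse
drug: vLDX
bioavailability: 0.964
ka_per_h: 0.8
clearance_l_per_h: 21.0
dose_mg: 50.0
doses_per_day: 1
days: 3
ec50_mg_per_l: 0.05
partition:
  gut_tissue: 3.0
  liver: 4.0
  kidney: 4.0
  brain: 4.0
  heart: 1.5
  lung: 2.0
  spleen: 1.5
  muscle: 1.5
  adipose: 3.0
  skin: 2.0
  bone: 1.0
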