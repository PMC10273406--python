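# Oral PK parameters for virtual methylphenidate (Medikinet IR), the vMPH drug.
# F is the published oral bioavailability; hepatic first-pass loss is folded
# into F and elimination is modelled as renal.
name: medikinet
drug: vMPH
bioavailability: 0.30
ka_per_h: 1.5
clearance_l_per_h: 39.0
dose_mg: 20.0
doses_per_day: 2
days: 3
ec50_mg_per_l: 0.01
partition:
  gut_tissue: 2.5
  liver: 3.0
  kidney: 3.0
  brain: 3.0
  heart: 1.5
  lung: 1.8
  spleen: 1.5
  muscle: 1.2
  adipose: 2.0
  skin: 1.5
  bone: 0.8
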