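# Reference-adult (70 kg) whole-body physiology for the 14-compartment PBPK model.
# Volumes in L, blood flows in L/h. "flow" is the arterial inflow to the tissue;
# the lung, arterial and venous pools carry the full cardiac output, and the gut
# lumen is not perfused. Perfused-tissue flows sum exactly to cardiac output
# (gut_tissue and spleen drain through the liver, whose total outflow is
# hepatic-artery + portal inflows).
reference_weight_kg: 70.0
cardiac_output_l_per_h: 350.0
compartments:
  gut_lumen:  {volume: 1.0,  flow: 0.0}
  gut_tissue: {volume: 1.2,  flow: 65.0}
  liver:      {volume: 1.8,  flow: 25.0}
  kidney:     {volume: 0.31, flow: 75.0}
  brain:      {volume: 1.45, flow: 45.0}
  heart:      {volume: 0.33, flow: 15.0}
  lung:       {volume: 0.5,  flow: 350.0}
  spleen:     {volume: 0.19, flow: 10.0}
  muscle:     {volume: 29.0, flow: 65.0}
  adipose:    {volume: 13.0, flow: 20.0}
  skin:       {volume: 3.3,  flow: 20.0}
  bone:       {volume: 10.0, flow: 10.0}
  arterial:   {volume: 1.7,  flow: 350.0}
  venous:     {volume: 3.9,  flow: 350.0}
# Uniform multipliers applied to every volume and flow after allometric
# weight scaling, so conservation invariants are preserved.
sex_multipliers: {male: 1.0, female: 0.92}
age_multipliers: {child: 1.0, adolescent: 1.0, adult: 1.0}
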