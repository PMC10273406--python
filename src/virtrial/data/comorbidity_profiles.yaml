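# The eight study comorbidity profiles (five common ADHD comorbidities, alone
# or in the stated combinations) plus the "none" main-group profile.
# Co-treatments name the drugs commonly prescribed for each condition.
# Molecular definitions are NOT stored here: the real ones are proprietary, so
# they are sampled synthetically from the working network at study-build time
# (see virtrial.synthetic.generate_comorbidity_profiles).
profiles:
  - name: none
    co_treatments: []
  - name: depression
    co_treatments: [fluoxetine, sertraline, citalopram]
  - name: anxiety
    co_treatments: [hydroxyzine, citalopram]
  - name: bipolar disorder
    co_treatments: [lithium, fluoxetine]
  - name: tics
    co_treatments: [guanfacine, aripiprazole, tiapride, haloperidol, risperidone]
  - name: binge eating disorder
    co_treatments: [fluoxetine]
  - name: binge eating disorder + anxiety
    co_treatments: [fluoxetine, hydroxyzine]
  - name: binge eating disorder + depression
    co_treatments: [fluoxetine, sertraline]
  - name: depression + anxiety
    co_treatments: [sertraline, citalopram, hydroxyzine]
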