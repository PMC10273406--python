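gene	protein_name	effect	vLDX	vMPH
TAAR1	Trace amine-associated receptor 1	1	ref41	-
SLC18A2	Synaptic vesicular amine transporter (VMAT2)	-1	ref41,ref42	-
SLC6A3	Sodium-dependent dopamine transporter (DAT)	-1	ref42	ref45
SLC6A2	Sodium-dependent noradrenaline transporter (NET)	-1	ref42,ref44	ref45
SLC6A4	Sodium-dependent serotonin transporter (SERT)	-1	ref42	-
MAOA	Amine oxidase (flavin-containing) A	-1	ref44,ref48	-
MAOB	Amine oxidase (flavin-containing) B	-1	ref44,ref48	-
HTR1A	5-hydroxytryptamine receptor 1A	1	-	ref49,ref50
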