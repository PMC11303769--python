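# name	mass_delta_Da	composition_delta	allowed_residues (Nterm = N-terminal placement)
Oxidation	15.994915	O:1	F,H,K,M,P,W,Y
Dioxidation	31.989830	O:2	F,M,P,W,Y
Deamidation	0.984016	H:-1,N:-1,O:1	N,Q,R
Phosphorylation	79.966331	H:1,O:3,P:1	S
Acetyl	42.010565	C:2,H:2,O:1	Nterm
Gln->pyro-Glu	-17.026549	H:-3,N:-1	Nterm,Q
Glu->pyro-Glu	-18.010565	H:-2,O:-1	Nterm,E
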