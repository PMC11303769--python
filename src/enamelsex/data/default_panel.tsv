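# id	sequence	mods	charge	reference_mz	source	saav_positions
Y1	LRYPYP		2	404.7212	AmelY	46,48
Y2	LRYPYPSY		2	529.7689	AmelY	46,48
X1	SMIRHPYP	2:Oxidation	2	508.7527	AmelX	44,46,48
X2	IRHPYPSY		2	516.7667	AmelX	46,48
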