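>AmelX_synthetic synthetic stand-in for a bovine amelogenin X isoform (marker context at Ser44/Ile46/His48); not the UniProt record
MGTWILFACLLGAAFAMPLPPHPGHPGYINFSYEVLTPLKWYQSMIRHPYPSYGYEPMGG
WLHHQIIPVLSQQHPPSHTLQPHHHLPVVPAQQPVAPQQPMMPVPGHHSMTPTQHHQPNL
PLPAQQPFQPQPVQPQPHQPLQPQPPVHPIQPLPPQPPLPPLFSMQPLSPILPELPLEAW
PATDKTKREEVD
>AmelY_synthetic synthetic stand-in for a bovine amelogenin Y isoform (marker context at Leu46/Tyr48); not the UniProt record
MGTWILFACLLGAAFAMPLPPHPGHPGYINFSYEVLTPLKWYQPMLRYPYPSYGYEPMGG
WLHHQIIPVVSQQTPQSHALQPHHHIPMVPAQQPGIPQQPMMPLPGQHSMTPTQHHQPNI
PPSAQQPFQPQPVQPQPHQPLQPQSPMHPIQPLAPQPPLPPLFSLQPLSPILPELPLEAW
PATDKTKREEVD
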