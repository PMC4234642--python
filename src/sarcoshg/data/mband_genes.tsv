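name	gene_id	fold_change
OBSCN	ENSOCUT00000011554	0.266
OBSL	ENSOCUT00000011142	0.171
Titin	ENSOCUT00000016899	0.265
Myopalladin	ENSOCUT00000009940	0.405
Myomesin-2	ENSOCUT00000013143	0.265
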