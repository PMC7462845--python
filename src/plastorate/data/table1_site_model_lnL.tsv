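gene	model	lnL	df
rps5	M7	-6492.11	2
rps5	M8	-6275.91	2
atpI	M7	-9013.33	2
atpI	M8	-8757.67	2
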