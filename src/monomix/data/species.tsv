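name	n_carbons	pKa
LA	12	7.44
MA	14	7.88
PA	16	8.34
SA	18	9.89
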