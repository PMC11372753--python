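pH	name	n_acid	n_base
2	LA	20	0
2	MA	40	0
2	PA	80	0
2	SA	60	0
7	LA	16	4
7	MA	36	4
7	PA	76	4
7	SA	60	0
8.2	LA	4	16
8.2	MA	12	28
8.2	PA	48	36
8.2	SA	58	2
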