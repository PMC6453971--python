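genome	reference_accession	reference_name	reference_genus	rep_identity_aa
LC386204	KT862223	Bovine faeces associated smacovirus 1	Huchismacovirus	46.86
LC386195	KT600068	Human feces smacovirus 2	Porprismacovirus	75.18
LC386196	GQ351274	Chimpanzee stool associated circular ssDNA virus	Porprismacovirus	64.48
LC386205	JX274036	Porcine stool associated circular virus	Porprismacovirus	81.07
LC386197	JX274036	Porcine stool associated circular virus	Porprismacovirus	83.95
LC386198	JX274036	Porcine stool associated circular virus	Porprismacovirus	81.48
LC386199	KT862221	Sheep faeces associated smacovirus 2	Porprismacovirus	42.08
LC386201	KT862218	Bovine faeces associated smacovirus 2	Porprismacovirus	39.24
LC386200	KT862218	Bovine faeces associated smacovirus 2	Porprismacovirus	40.92
LC386202	KT862218	Bovine faeces associated smacovirus 2	Porprismacovirus	39.66
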