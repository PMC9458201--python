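# units=kcal/mol
# description=per-replica absolute binding free energies from four independent non-equilibrium TI replicas
system	replica	value_kcal_per_mol	uncertainty_kcal_per_mol
2HP-b-CD	1	-1.45	0.46
2HP-b-CD	2	-1.39	0.28
2HP-b-CD	3	-1.55	0.40
2HP-b-CD	4	-1.21	0.36
2,6Me-b-CD	1	-5.21	0.37
2,6Me-b-CD	2	-5.14	0.28
2,6Me-b-CD	3	-4.53	0.45
2,6Me-b-CD	4	-5.47	0.39
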