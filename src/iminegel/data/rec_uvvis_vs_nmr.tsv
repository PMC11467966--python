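method	aldehyde	amine	salt_total_mM	conc0_mM	k1_L_mol_s	k1_sd	k_minus1_s	k_minus1_sd	Keq_L_mol	Keq_sd
uvvis	2	5	159	0.5	0.058	0.002	5.2e-5	2.5e-5	1.3e3	0.6e3
uvvis	2	7	159	0.5	0.009	0.002	9.1e-5	1.2e-5	1.0e2	0.1e2
nmr	2	5	57	5	0.005	1e-5	2.9e-5	1e-6	1.9e2	6
nmr	2	7	57	24	0.0009	3e-5	1.19e-4	9e-6	7	1
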