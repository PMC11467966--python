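aldehyde	amine	conc_uM	epsilon_L_mol_cm	k1_L_mol_s	k1_sd	k_minus1_s	k_minus1_sd	Keq_L_mol	Keq_sd	method	aggregation
3	4	100									no_reaction
3	5	100	2200	9.50	0.30	8.3e-6	5.1e-6	1.6e6	1.3e6	free_fit	per_replicate_mean
3	6	100	4200	10.30	0.30	3.65e-4	6e-6	2.8e4	1e3	free_fit	per_replicate_mean
3	7	100	8600	0.69	0.03	5.7e-5	3e-6	1.20e4	0.7e3	free_fit	per_replicate_mean
3	8	100	9700	4.00	0.20	1.1e-6	3e-7	3.7e6	1.1e6	constrained_fit	global_fit
3	9	50	14200	0.75	0.04	1.1e-5	8e-6	8.7e4	6e4	constrained_fit	per_replicate_mean
2	5	500	950	0.058	0.002	5.2e-5	2.5e-5	1.3e3	0.6e3	free_fit	per_replicate_mean
2	6	100	2100	0.099	0.022	4.5e-4	7e-5	2.2e2	0.6e2	free_fit	per_replicate_mean
2	7	500	1870	0.009	0.002	9.1e-5	1.2e-5	1.0e2	0.1e2	free_fit	per_replicate_mean
2	8	100	8700	0.12	0.01	3.15e-4	1.1e-5	3.9e2	0.2e2	free_fit	per_replicate_mean
2	9	50	7200	0.059	0.0003					irreversible_fit	per_replicate_mean
1	5	100	2850	0.95	0.08	1.06e-4	6e-6	9.0e3	0.5e3	free_fit	per_replicate_mean
1	6	100	4750	0.63	0.02	1.60e-4	1e-6	3.9e3	0.1e3	free_fit	per_replicate_mean
1	7	100	11100	0.124	0.003	5.7e-5	1e-6	2.2e3	0.1e3	free_fit	per_replicate_mean
1	8	100	10200	0.570	0.015	7.6e-5	2e-6	7.5e3	0.4e3	free_fit	per_replicate_mean
1	9	50	20500	0.051	0.003	5.2e-6	3.4e-6	1.3e4	7e3	free_fit	per_replicate_mean
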