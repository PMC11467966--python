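amine	N_eV	natural_charge_e	dG1_kcal_mol	dG2_kcal_mol	drG_kcal_mol
4	2.887	-0.960	10.73	-11.61	-0.87
5	2.589	-0.634	9.01	-16.78	-7.77
6	2.903	-0.774	10.89	-18.02	-7.13
7	2.683	-0.747	6.39	-6.94	-0.54
8	2.828	-0.761	8.53	-16.39	-7.86
9	3.116	-0.754	10.54	-16.24	-5.70
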