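# Restrained-FEP inputs and published constants for sevoflurane binding to
# the open Kv1.2 channel: 12 sites in three regions of the homotetramer,
# double occupancy resolved everywhere except the extracellular face.
# level 1 rows: k and the single-ligand work W*_1; level 2 rows: the
# doubly-occupied-column k and the second-step work W*_2|1 (cumulative
# W*_2 = W*_1 + W*_2|1). K_printed / dG0_printed are the published
# constants (mM^-n) and standard free energies (kcal/mol) for cross-checks;
# the excess chemical potential behind them is -0.1 kcal/mol.
site_id	region	level	k	work_step	error	K_printed	dG0_printed
1	S6P-helix	1	0.053	-4.5	0.2	5.93E-01	-3.8
1	S6P-helix	2	0.196	-3.6	0.2	5.41E+00	-5.1
2	S6P-helix	1	0.141	-4.7	0.2	1.92E-01	-3.1
2	S6P-helix	2	0.137	-4.3	0.2	9.71E+00	-5.4
3	S6P-helix	1	0.084	-5.0	0.2	6.86E-01	-3.9
3	S6P-helix	2	0.084	-3.8	0.3	3.14E+01	-6.1
4	S6P-helix	1	0.036	-3.8	0.3	3.26E-01	-3.4
4	S6P-helix	2	0.174	-3.3	0.4	2.14E+00	-4.5
5	Ext-face	1	0.530	1.5	0.4	7.57E-07	4.3
6	Ext-face	1	0.453	-0.8	0.4	4.63E-05	1.8
7	Ext-face	1	0.283	-0.8	0.4	9.36E-05	1.4
8	Ext-face	1	0.332	-4.2	0.5	2.28E-02	-1.9
9	S4S5-linker	1	0.061	-6.4	0.2	1.18E+01	-5.6
9	S4S5-linker	2	0.004	-4.0	0.3	7.45E+04	-10.7
10	S4S5-linker	1	0.127	-7.5	0.0	2.51E+01	-6.0
10	S4S5-linker	2	0.004	-5.2	0.2	1.18E+06	-12.4
11	S4S5-linker	1	0.037	-6.7	0.3	4.19E+01	-6.3
11	S4S5-linker	2	0.003	-7.0	0.3	4.97E+07	-14.6
12	S4S5-linker	1	0.058	-5.6	0.3	3.30E+00	-4.8
12	S4S5-linker	2	0.003	-6.1	0.3	1.00E+06	-12.3
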