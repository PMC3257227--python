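# Published per-residue H/D exchange summary for the 124-residue monomer
# at pH 5.7, 300 K: observed rate (1/hr), protection factor, opening free
# energy (kcal/mol). Used as reference input for consistency checks.
residue	k_obs	k_obs_err	P	dG_op	dG_op_err
PHE8	0.114	0.046	8.87E+03	5.40	0.04
GLU9	0.273	0.015	1.82E+03	4.46	0.02
ARG10	0.130	0.018	9.03E+03	5.41	0.06
GLN11	0.026	0.015	9.75E+04	6.82	0.04
HIS12	0.038	0.016	2.48E+05	7.38	0.06
ASP14	0.190	0.027	4.83E+03	5.04	0.01
SER21	0.040	0.100	1.56E+05	7.01	0.03
CYS26	0.109	0.057	4.86E+04	6.41	0.02
LEU28	0.640	0.073	1.15E+03	4.18	0.02
MET30	0.011	0.016	1.53E+05	7.09	0.02
CYS31	0.134	0.019	4.54E+04	6.37	0.01
CYS32	2.220	0.570	6.13E+03	5.18	0.02
ARG33	0.249	0.028	1.85E+04	5.84	0.01
LYS34	0.262	0.017	7.70E+03	5.32	0.05
LYS41	0.200	0.084	1.75E+04	5.80	0.04
VAL43	0.469	0.101	3.39E+02	3.46	0.06
ASN44	0.031	0.010	9.62E+04	6.81	0.09
GLU49	0.044	0.015	6.78E+04	6.61	0.01
ASP53	0.725	0.120	9.90E+02	4.10	0.03
ALA56	0.059	0.006	2.96E+04	6.12	0.02
VAL57	0.003	0.007	7.90E+04	6.70	0.04
CYS58	0.010	0.006	3.39E+05	7.56	0.01
SER59	0.425	0.052	2.12E+04	5.91	0.01
LYS61	0.062	0.075	3.11E+04	6.14	0.02
GLN69	0.026	0.072	8.70E+04	6.76	0.04
GLN74	0.005	0.014	3.43E+05	7.57	0.05
SER77	0.011	0.044	3.73E+05	7.62	0.03
ARG80	0.191	0.026	1.08E+04	5.52	0.02
ILE81	0.007	0.015	5.91E+04	6.53	0.06
THR82	0.005	0.021	1.34E+05	7.01	0.05
ASP83	0.182	0.025	6.19E+03	5.19	0.03
CYS84	0.027	0.017	1.21E+05	6.95	0.04
ARG85	0.016	0.015	2.88E+05	7.47	0.01
GLU86	0.083	0.016	8.63E+03	5.38	0.09
SER89	0.033	0.025	1.40E+05	7.04	0.03
LYS91	0.038	0.013	6.38E+04	6.57	0.10
ALA96	0.621	0.112	6.21E+03	5.19	0.08
TYR97	0.252	0.034	2.84E+03	4.73	0.02
THR100	0.057	0.015	3.15E+04	6.15	0.06
VAL102	0.023	0.010	1.85E+04	5.83	0.02
LYS104	0.014	0.079	5.44E+04	6.48	0.04
ILE106	0.008	0.013	1.61E+05	7.12	0.02
ALA109	0.014	0.014	6.89E+04	6.62	0.07
GLY111	0.322	0.086	2.21E+04	5.94	0.06
VAL118	0.012	0.022	1.30E+04	5.63	0.02
HIS119	0.026	0.012	1.66E+05	7.14	0.05
VAL124	0.360	0.038	3.26E+01	2.07	0.04
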