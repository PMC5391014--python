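subject	sr_inv_pf	sr_ff_swlda	sr_ff_pf	acc_inv_pf	acc_ff_swlda	acc_ff_pf	ccpm_inv_pf	ccpm_ff_swlda	ccpm_ff_pf
P	13.36	11.07	12.95	90.00	100.00	100.00	12.02	11.07	12.95
Q	10.64	10.29	11.70	96.67	90.00	100.00	10.29	9.26	11.70
R	12.58	10.88	13.35	86.67	96.67	96.67	10.90	10.51	12.90
S	8.21	9.39	11.57	96.67	96.67	100.00	7.93	9.07	11.57
T	8.30	9.21	11.61	70.00	80.00	90.00	5.81	7.37	10.45
U	12.09	9.57	12.94	96.67	96.67	96.67	11.69	9.26	12.51
V	9.96	11.61	11.75	100.00	100.00	100.00	9.96	11.61	11.75
W	8.91	7.81	10.79	96.67	93.33	93.33	8.61	7.29	10.07
X	11.53	9.81	10.06	83.33	100.00	93.33	9.61	9.81	9.39
Y	7.83	8.13	12.95	100.00	96.67	90.00	7.83	7.86	11.65
Average	10.34	9.78	11.97	91.67	95.00	96.00	9.46	9.31	11.49
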