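subject	sr_inv_pf	sr_ff_pf	acc_inv_pf	acc_ff_pf	ccpm_inv_pf	ccpm_ff_pf
P	11.02	10.96	98.18	100.00	10.82	10.96
Q	7.36	12.20	75.00	100.00	5.52	12.20
R	9.96	11.90	85.71	100.00	8.54	11.90
S	6.44	11.66	100.00	89.58	6.44	10.44
T	5.70	9.03	61.90	80.77	3.53	7.30
U	10.00	10.45	79.59	100.00	7.96	10.45
V	11.14	12.78	90.38	100.00	10.07	12.78
W	6.27	10.62	77.42	75.47	4.86	8.01
X	9.27	11.63	97.83	98.25	9.07	11.42
Y	7.38	10.34	88.89	98.04	6.56	10.14
Average	8.45	11.16	85.49	94.21	7.33	10.56
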