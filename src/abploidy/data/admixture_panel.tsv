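individual_id	lineages	proportions	lineage_ploidies	expected_f1_printed	expected_printed	predicted_ploidy	flow_estimate	location
Y44	AU/CN	0.24/0.76	8/4	6.0	5.0	6	?	China
K13	AU/CN	0.80/0.20	8/4	6.0	7.2	8	8-10x	Russia
Y43	AU/CN	0.75/0.25	8/4	6.0	7.0	8	?	China
Y49	AU/CN	0.77/0.23	8/4	6.0	7.1	8	?	China
Y48	AU/USland	0.73/0.27	8/6	7.0	7.5	8	?	China
Y55	AU/CN/EU	0.72/0.09/0.18	8/4/4	6.0	6.8	4	?	China
Y3	Med/EU/CN	0.62/0.36/0.01	4/4/4	4.0	4.0	8	8x	South Africa
F2	Med/EU/CN	0.63/0.35/0.01	4/4/4	4.0	4.0	8	8x	South Africa
H2	Med/EU	0.59/0.41	4/4	4.0	4.0	6	6x	Greece
Y36	Med/EU	0.59/0.41	4/4	4.0	4.0	8	8x	South Africa
K12	USnat/AU	0.65/0.35	4/8	6.0	5.4	4	4x	Russia
A7	EU/Med	0.91/0.09	4/4	4.0	4.0	8	8x	Romania
K2	EU/Med	0.92/0.08	4/4	4.0	4.0	6	6x	Romania
A8	EU/Med	0.95/0.05	4/4	4.0	4.0	6	6x	Romania
B2	EU/Med	0.94/0.06	4/4	4.0	4.0	6	6x	Romania
A5	EU/Med/CN	0.89/0.09/0.02	4/4/4	4.0	4.0	8	8x	Hungary
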