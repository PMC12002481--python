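primer	species	tm_predicted_celsius	tm_measured_celsius	difference
psaA-2	Navicula sp.	81.68	82.38	0.7
psaA-2	Odontella sp.	82.05	82.54	0.49
psaA-2	Skeletonema sp.	82.2	82.56	0.36
psaA-2	Chaetoceros sp.	82.78	83.05	0.27
psaA-2	Nitzschia sp.	81.97	82.34	0.37
Dia18S	Navicula sp.	83.3	84.43	1.13
Dia18S	Skeletonema sp.	81.5	82.91	1.41
Dia18S	Nitzschia sp.	84.75	84.14	0.61
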