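primer	species	gc_percent	n	dH_kcal_per_mol	dS_cal_per_K_mol
UPA99	Navicula sp.	42.19	63	-510.4	-1390
UPA99	Odontella sp.	39.01	63	-506.8	-1385.8
UPA99	Skeletonema sp.	41.67	59	-467.8	-1272.8
UPA99	Chaetoceros sp.	42.19	63	-510.3	-1388.9
UPA99	Nitzschia sp.	40.63	63	-511.3	-1395.3
18S-V7	Navicula sp.	47.73	87	-706.9	-1898.3
18S-V7	Odontella sp.	53.26	91	-750.4	-2010.6
18S-V7	Skeletonema sp.	49.45	90	-743.7	-1997.9
18S-V7	Chaetoceros sp.	45.45	87	-708.3	-1912.9
18S-V7	Nitzschia sp.	47.19	88	-715.2	-1914.6
ND	Navicula sp.	37.18	77	-617	-1681.8
ND	Odontella sp.	34.62	77	-614.4	-1678.5
ND	Skeletonema sp.	34.62	77	-615.2	-1681.5
ND	Chaetoceros sp.	35.90	77	-619	-1688.5
ND	Nitzschia sp.	34.62	77	-614.4	-1678.5
Primer1	Navicula sp.	44.30	148	-1219.8	-3283.5
Primer1	Odontella sp.	51.61	154	-1275.6	-3283.5
Primer1	Skeletonema sp.	44.00	149	-1216.3	-3283.1
Primer1	Chaetoceros sp.	49.01	150	-1237.2	-3318.3
Primer1	Nitzschia sp.	48.03	151	-1232.8	-3318.3
psaA-2	Navicula sp.	47.83	114	-932	-2507
psaA-2	Odontella sp.	47.83	114	-934.6	-2512.9
psaA-2	Skeletonema sp.	47.83	114	-934.6	-2512.8
psaA-2	Chaetoceros sp.	48.28	115	-949.6	-2549.2
psaA-2	Nitzschia sp.	47.83	114	-932	-2507.1
Dia18S	Navicula sp.	51.02	97	-800.7	-2135.7
Dia18S	Skeletonema sp.	46.00	99	-800.9	-2153
Dia18S	Nitzschia sp.	55.24	104	-865.2	-2303.2
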