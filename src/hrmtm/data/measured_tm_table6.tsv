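primer	species	tm_measured_celsius
UPA99	Navicula sp.	79.03
UPA99	Odontella sp.	78.37
UPA99	Skeletonema sp.	79.27
UPA99	Chaetoceros sp.	79.17
UPA99	Nitzschia sp.	79.17
18S-V7	Navicula sp.	81.35
18S-V7	Odontella sp.	82.40
18S-V7	Skeletonema sp.	82.85
18S-V7	Chaetoceros sp.	81.30
18S-V7	Nitzschia sp.	82.03
ND	Navicula sp.	76.80
ND	Odontella sp.	76.42
ND	Skeletonema sp.	76.50
ND	Chaetoceros sp.	77.50
ND	Nitzschia sp.	76.57
Primer1	Navicula sp.	83.40
Primer1	Odontella sp.	84.72
Primer1	Skeletonema sp.	82.43
Primer1	Chaetoceros sp.	84.42
Primer1	Nitzschia sp.	84.08
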