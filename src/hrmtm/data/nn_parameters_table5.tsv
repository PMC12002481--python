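name	dH_kcal_per_mol	dS_cal_per_K_mol
AA/TT	-7.9	-22.2
AT/TA	-7.2	-20.4
TA/AT	-7.2	-21.3
CA/GT	-8.5	-22.7
GT/CA	-8.4	-22.4
CT/GA	-7.8	-21.0
GA/CT	-8.2	-22.2
CG/GC	-10.6	-27.2
GC/CG	-9.8	-24.4
GG/CC	-8.0	-19.9
init_terminal_GC	0.1	-2.8
init_terminal_AT	2.3	4.1
symmetry_correction	0	-1.4
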