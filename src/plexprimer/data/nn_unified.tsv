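# Unified Watson-Crick nearest-neighbor parameters (1 M NaCl reference state)
# entry	dH_kcal_per_mol	dS_cal_per_mol_K	dG37_kcal_per_mol
AA	-7.9	-22.2	-1.0147
AC	-8.4	-22.4	-1.4526
AG	-7.8	-21.0	-1.2869
AT	-7.2	-20.4	-0.8729
CA	-8.5	-22.7	-1.4596
CC	-8.0	-19.9	-1.8280
CG	-10.6	-27.2	-2.1639
CT	-7.8	-21.0	-1.2869
GA	-8.2	-22.2	-1.3147
GC	-9.8	-24.4	-2.2323
GG	-8.0	-19.9	-1.8280
GT	-8.4	-22.4	-1.4526
TA	-7.2	-21.3	-0.5938
TC	-8.2	-22.2	-1.3147
TG	-8.5	-22.7	-1.4596
TT	-7.9	-22.2	-1.0147
INIT_AT	2.3	4.1	1.0284
INIT_GC	0.1	-2.8	0.9684
SYMMETRY	0.0	-1.4	0.4342
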