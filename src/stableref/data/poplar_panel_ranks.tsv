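# Published per-method stability values and ordinal ranks for the 19 poplar
# candidate reference genes that passed primer QC, as reported by the four
# standard RT-qPCR stability tools, plus the published geometric-mean
# consensus. Ties were printed as shared ranks by the original report.
gene	bestkeeper_value	bestkeeper_rank	deltact_value	deltact_rank	genorm_value	genorm_rank	normfinder_value	normfinder_rank	geomean_published	final_rank_published
SSU_S8e	0.68	2	0.84	1	0.57	7	0.28	1	1.93	1
RA	0.73	4	0.87	2	0.53	6	0.38	2	3.31	2
LSU_L5e	0.72	3	0.92	4	0.45	5	0.53	4	3.94	3
20S_PSU	0.8	8	1.02	7	0.21	1	0.77	9	4.74	4
CDPK	0.8	8	0.9	3	0.64	8	0.44	3	5.05	5
HIS	0.75	6	0.93	5	0.78	10	0.56	5	6.22	6
ACT_iso	0.73	4	1.09	11	0.32	3	0.87	12	6.31	7
SSU_S4e	0.88	14	1.11	13	0.21	1	0.92	14	7.23	8
18S_RNA	0.55	1	1.2	16	0.94	15	0.94	16	7.87	9
IF5A	0.81	10	1	6	0.83	11	0.69	6	7.93	10
EF1b	0.79	7	1.03	8	0.87	12	0.69	6	8.28	11
ACT_uni	0.82	11	1.06	9	0.71	9	0.72	8	9.19	12
26S_PRS	0.84	12	1.13	14	0.36	4	0.93	15	10.02	13
CYP	0.88	14	1.08	10	0.9	13	0.81	10	11.61	14
CDC2	0.86	13	1.1	12	0.92	14	0.85	11	12.45	15
UBQ10-5	1.03	17	1.18	15	0.98	16	0.91	13	15.18	16
UBQ10-9	1.21	18	1.26	17	1.01	17	1.03	17	17.24	17
DnaJ_A2	0.97	16	1.33	19	1.07	19	1.11	19	18.2	18
TIF5A_iso	1.37	19	1.3	18	1.04	18	1.1	18	18.24	19
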