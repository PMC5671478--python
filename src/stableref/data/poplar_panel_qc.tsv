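# RT-qPCR primer-panel QC values for a 21-assay poplar stem (xylem/phloem,
# fungal-canker inoculated vs control) validation panel: per-assay PCR
# amplification efficiency (per-cycle factor, 2 = perfect doubling) with its
# standard deviation, and R^2 of the calibration curve.
gene	efficiency	efficiency_sd	r2
SSU_S4e	1.931	0.022	0.999
SSU_S8e	1.902	0.019	0.998
DnaJ_A2	1.825	0.029	0.996
CDPK	1.928	0.018	0.997
26S_PRS	1.945	0.021	0.998
UbqCE	1.615	0.065	0.993
LSU_L5e	1.874	0.018	0.999
20S_PSU	1.945	0.018	0.996
TIF5A_uni	1.605	0.040	0.995
TIF5A_iso	1.860	0.020	0.996
ACT_iso	1.856	0.026	0.997
ACT_uni	1.926	0.017	0.996
EF1b	1.885	0.015	0.997
UBQ10-9	1.919	0.019	0.998
UBQ10-5	1.923	0.018	0.997
18S_RNA	1.973	0.031	0.999
CDC2	1.919	0.019	0.996
HIS	1.897	0.015	0.999
CYP	1.923	0.019	0.996
IF5A	1.913	0.013	0.997
RA	1.926	0.018	0.999
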