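# Default tripeptide probe library (synthetic stand-in).
# Only P3 (LFF) and P17 (NFW) are publicly disclosed probe sequences;
# P2/P12/P13 are known to start with D/N/N respectively. The remaining
# probes are constructed tripeptides skewed toward rare amino acids
# (encoded by 1-3 codons), matching the character of the original library.
P1	CMW
P2	DWC
P3	LFF
P4	WHM
P5	CYF
P6	MCW
P7	FWH
P8	HMY
P9	YCH
P10	WFC
P11	MHW
P12	NCM
P13	NWY
P14	HYW
P15	FMC
P16	YWF
P17	NFW
P18	WCH
P19	MFY
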