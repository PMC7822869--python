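immune_response	synthetic demonstration set (not a curated database)	CX3CL1	ZC3H12A	TNFSF13	OSMR	IRF1	TLR2	TXNIP	PLSCR1	S100A9	C1QB	CD68	TYROBP	FPR1
cell_death	synthetic demonstration set (not a curated database)	RIPK1	DIABLO	GADD45A	DAXX	PHLDA2	CDIP1	MDM4	BCL7B	HSPD1	ZFP36
nervous_system_development	synthetic demonstration set (not a curated database)	SYN1	SYN2	SEMA6A	LIMK1	CDK5R2	NDE1	HES5	FZD8	WNT7B	GUCA1B	MOG	HAPLN2
housekeeping_like	synthetic demonstration set (not a curated database)	GAPDH	ACTB	RPL6	TAF6	FCF1	MRPL34
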