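# symbol	synonym
IFNG	IFN-gamma
IFNG	interferon gamma
IFNG	interferon-gamma
IFNA1	IFN-alpha
IFNA1	IFN-alpha 1
IFNA1	interferon alpha
TNF	TNF-alpha
TNF	tumor necrosis factor
IL2	IL-2
IL2	interleukin 2
IL4	IL-4
IL5	IL-5
IL6	IL-6
IL7	IL-7
IL8	IL-8
IL10	IL-10
IL12B	IL-12
IL13	IL-13
IL18	IL-18
CSF2	GM-CSF
NFKB1	NF-kappaB
CD4	
CD8A	CD8
CD28	
CD40	
CD40LG	CD40 ligand
CD46	
CD86	
C3	complement C3
TLR2	toll-like receptor 2
TLR4	toll-like receptor 4
TLR6	toll-like receptor 6
TP53	p53
FCGR2B	CD32
EIF2AK2	PKR
NCAM1	CD56
CXCL10	IP-10
CCL2	MCP-1
HSPD1	HSP60
TPBG	5T4
GNLY	granulysin
TNFSF10	TRAIL
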