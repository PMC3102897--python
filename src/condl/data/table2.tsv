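# vaccine	category	num_genes	genes
Fluzone	Inactivated viral vaccine	4	IFNA1,CD4,CD8A,IL10
Vaxigrip	Inactivated viral vaccine	4	IFNA1,CD4,CD8A,TNF
Engerix-B	Inactivated viral vaccine	3	IFNA1,CD4,IL2
FSME - IMMUN	Inactivated viral vaccine	3	CD4,IL6,TNF
Fluarix	Inactivated viral vaccine	1	IFNA1
Havrix	Inactivated viral vaccine	1	CD4
Vaqta	Inactivated viral vaccine	1	CD4
BCG Vaccine	Live attenuated bacterial vaccine	31	HSPD1,IL18,CCL2,IL5,CD40,EIF2AK2,TLR4,IL13,CD40LG,CD86,IFNG,CSF2,CXCL10,TP53,FCGR2B,NFKB1,IFNA1,GNLY,IL2,IL10,IL4,CD28,CD4,C3,IL6,CD8A,IL8,TLR2,IL7,TNF,NCAM1
LVS	Live attenuated bacterial vaccine	17	CCL2,CD40,TLR4,CD86,IFNG,IFNA1,NFKB1,IL10,IL2,IL4,CD4,C3,IL6,IL8,CD8A,TLR2,TNF
Brucella strain 19	Live attenuated bacterial vaccine	5	IFNA1,CD4,CD8A,IL2,IL10
RB51	Live attenuated bacterial vaccine	2	CD4,CD8A
CVD 1207	Live attenuated bacterial vaccine	2	IL4,IL5
CVD 1208	Live attenuated bacterial vaccine	1	IFNG
CVD 1208S	Live attenuated bacterial vaccine	1	IFNG
Rotarix	Live attenuated viral vaccine	2	CD4,CD8A
RotaTeq	Live attenuated viral vaccine	2	CD4,CD8A
Varilrix	Live attenuated viral vaccine	2	CD4,CD8A
Varivax	Live attenuated viral vaccine	1	CD4
ProQuad	Live attenuated viral vaccine	1	CD4
Dryvax	Other live vaccine	5	IFNA1,CD4,CD8A,IFNG,IL2
TICE BCG	Other live vaccine	3	IFNA1,CD4,CD8A
RTS,S/AS02A	Subunit vaccine	7	IFNA1,IL4,CD4,IFNG,IL5,CD8A,IL2
Pneumo 23	Subunit vaccine	3	IFNA1,IL4,CD4
FMP1/AS02A	Subunit vaccine	2	IFNA1,IL5
Gardasil	Subunit vaccine	2	CD4,IL2
ActHIB	Subunit vaccine	1	CD4
Infanrix	Subunit vaccine	1	IFNA1
Menactra	Subunit vaccine	1	C3
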