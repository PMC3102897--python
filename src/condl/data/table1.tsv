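# gene	degree	eigenvector	betweenness	closeness	star	reference_pmid
IL2	+	+	+	+		8459207
TNF	+	+	+	+		16446013
IL10	+	+	+	+		10930151
IL6	+	+	+	+		10225849
IL4	+	+	+	+		8519092
CSF2	+	+	+	+		19459853
IL8	+	+	+	+		11378044
IL5	+	+	-	+		11138639
NFKB1	+	+	+	+	*	16971487
IL13	+	+	+	+		12232042
CD4	+	+	+	+		17298856
TLR2	+	+	+	-	*	12874299
IL7	+	-	+	+		17496983
IL18	+	-	-	+		19467215
EIF2AK2	+	+	+	-		19596385
CD40LG	+	+	+	+		11403919
CD40	+	+	-	-		11403919
CD28	+	+	-	-		12594842
C3	+	+	+	-		19477524
TLR4	+	-	-	-	**	12874299
TP53	-	+	-	-	**	10379742
FCGR2B	-	+	-	-	**	12874345
CD46	-	+	+	-		11757799
NCAM1	-	-	+	+	*	16316416
CXCL10	-	-	+	-	*	10799249
CD86	-	-	+	-	*	12594842
HSPD1	-	-	+	-		12218165
IFNA1	-	-	-	+		19667099
CCL2	-	-	-	+	*	19833737
TPBG	-	-	-	+		16630022
GNLY	-	-	-	+		10644038
CD8A	-	-	-	+		18425263
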