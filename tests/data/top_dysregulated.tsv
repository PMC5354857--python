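gene_id	biotype	log2fc	status
RP3-404K8.2	lncRNA	-12.5289	down
AC106870.2	lncRNA	-10.6285	down
LINC00657	lncRNA	9.9658	up
RP1-309H15.2	lncRNA	-9.3248	down
AC073284.4	lncRNA	-9.0888	down
RP11-582J16.5	lncRNA	9.0239	up
TTN-AS1	lncRNA	8.966	up
AC133785.1	lncRNA	-8.8453	down
RP11-598C10.1	lncRNA	-8.4886	down
RP11-532N4.2	lncRNA	-8.2682	down
RP11-554D14.7	lncRNA	-8.0883	down
AC012307.2	lncRNA	-7.7326	down
RP11-398J5.1	lncRNA	-7.6951	down
RP11-166D19.1	lncRNA	6.6439	up
AC005550.4	lncRNA	6.5819	up
RP11-246K15.1	lncRNA	6.2735	up
KCNQ1OT1	lncRNA	5.8239	up
RP11-545D19.1	lncRNA	4.454	up
RP11-403I13.4	lncRNA	4.3186	up
IFNG-AS1	lncRNA	4.2951	up
POMC	mRNA	-14.4189	down
GH1	mRNA	-13.8967	down
GH2	mRNA	-13.0740	down
PRL	mRNA	-12.2965	down
FGFRL1	mRNA	-11.8589	down
ARHGEF28	mRNA	-10.9256	down
DFNA5	mRNA	-10.2130	down
CCDC144A	mRNA	-10.1246	down
MGAT2	mRNA	9.9658	up
H1FX	mRNA	9.9658	up
SF3B5	mRNA	9.9658	up
BTG2	mRNA	9.9658	up
PPIG	mRNA	9.9658	up
SLC6A15	mRNA	-8.7415	down
GAL	mRNA	-8.5745	down
ALPK2	mRNA	8.4247	up
SCGB1A1	mRNA	7.4549	up
CXCL13	mRNA	7.2726	up
ZNF804A	mRNA	5.8067	up
ZBTB41	mRNA	5.4197	up
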