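ligand	receptor	pathway	rank	source	mammalian_orthologs	ligand_annotation	receptor_annotation
upd1	dome	JAK-STAT	high	literature	IL6R|IL6ST	signal peptide	
upd2	dome	JAK-STAT	moderate	ortholog-mapped	IL6R|IL6ST		single-pass TM
upd3	dome	JAK-STAT	low	structure-screen	IL6|IL6R|IL6ST		single-pass TM
upd3	Lat	JAK-STAT	high	literature	IL6	signal peptide	
upd1	Lat	JAK-STAT	moderate	ortholog-mapped			single-pass TM
Dl	N	Notch	high	literature	DLL1|NOTCH1	signal peptide	
Ser	N	Notch	moderate	ortholog-mapped	NOTCH1		single-pass TM
Dl	Lrt	Notch	low	structure-screen	DLL1		single-pass TM
Ser	Lrt	Notch	high	literature		signal peptide	
hh	ptc	Hedgehog	high	literature	SHH|PTCH1	signal peptide	
hh	smo	Hedgehog	moderate	ortholog-mapped	SHH		single-pass TM
hh	ihog	Hedgehog	low	structure-screen	SHH		single-pass TM
hh	boi	Hedgehog	high	literature	SHH	signal peptide	
wg	fz	Wnt	high	literature	WNT1|FZD1	signal peptide	
wg	fz2	Wnt	moderate	ortholog-mapped	WNT1		single-pass TM
Wnt2	fz	Wnt	low	structure-screen	FZD1		single-pass TM
Wnt4	fz2	Wnt	high	literature		signal peptide	
Wnt5	drl	Wnt	moderate	ortholog-mapped			single-pass TM
Wnt6	fz4	Wnt	low	structure-screen			single-pass TM
spi	Egfr	EGFR	high	literature	TGFA|EGFR	signal peptide	
grk	Egfr	EGFR	moderate	ortholog-mapped	EGFR		single-pass TM
vn	Egfr	EGFR	low	structure-screen	EGFR		single-pass TM
Krn	Egfr	EGFR	high	literature	EGFR	signal peptide	
bnl	btl	FGF	high	literature	FGF1|FGFR1	signal peptide	
pyr	htl	FGF	moderate	ortholog-mapped			single-pass TM
ths	htl	FGF	low	structure-screen			single-pass TM
Pvf1	Pvr	PVR	high	literature	PDGFA|VEGFA|PDGFRA	signal peptide	
Pvf2	Pvr	PVR	moderate	ortholog-mapped	PDGFRA		single-pass TM
Pvf3	Pvr	PVR	low	structure-screen	PDGFRA		single-pass TM
dpp	tkv	TGF-beta	high	literature	BMP2|BMP4|BMPR1A	signal peptide	
dpp	put	TGF-beta	moderate	ortholog-mapped	BMP2|BMP4		single-pass TM
gbb	sax	TGF-beta	low	structure-screen			single-pass TM
gbb	tkv	TGF-beta	high	literature	BMPR1A	signal peptide	
scw	sax	TGF-beta	moderate	ortholog-mapped			single-pass TM
daw	babo	TGF-beta	low	structure-screen			single-pass TM
Ilp2	InR	Insulin	high	literature	INS|IGF1|INSR	signal peptide	
Ilp3	InR	Insulin	moderate	ortholog-mapped	INSR		single-pass TM
Ilp5	InR	Insulin	low	structure-screen	INSR		single-pass TM
Ilp6	InR	Insulin	high	literature	INSR	signal peptide	
spz	Tl	Toll	high	literature		signal peptide	
spz3	Toll-7	Toll	moderate	ortholog-mapped			single-pass TM
spz5	Toll-6	Toll	low	structure-screen			single-pass TM
spz6	Toll-8	Toll	high	literature		signal peptide	
sli	robo1	Slit-Robo	high	literature	SLIT2|ROBO1	signal peptide	
sli	robo2	Slit-Robo	moderate	ortholog-mapped	SLIT2		single-pass TM
sli	robo3	Slit-Robo	low	structure-screen	SLIT2		single-pass TM
CadN	CadN	Adhesion	high	literature		signal peptide	
Fas2	Fas2	Adhesion	moderate	ortholog-mapped			single-pass TM
Fas3	Fas3	Adhesion	low	structure-screen			single-pass TM
ed	ed	Adhesion	high	literature		signal peptide	
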