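pathway	gene	role
JAK-STAT	upd1	ligand
JAK-STAT	dome	receptor
JAK-STAT	upd2	ligand
JAK-STAT	upd3	ligand
JAK-STAT	Lat	receptor
Notch	Dl	ligand
Notch	N	receptor
Notch	Ser	ligand
Notch	Lrt	receptor
Hedgehog	hh	ligand
Hedgehog	ptc	receptor
Hedgehog	smo	receptor
Hedgehog	ihog	receptor
Hedgehog	boi	receptor
Wnt	wg	ligand
Wnt	fz	receptor
Wnt	fz2	receptor
Wnt	Wnt2	ligand
Wnt	Wnt4	ligand
Wnt	Wnt5	ligand
Wnt	drl	receptor
Wnt	Wnt6	ligand
Wnt	fz4	receptor
EGFR	spi	ligand
EGFR	Egfr	receptor
EGFR	grk	ligand
EGFR	vn	ligand
EGFR	Krn	ligand
FGF	bnl	ligand
FGF	btl	receptor
FGF	pyr	ligand
FGF	htl	receptor
FGF	ths	ligand
PVR	Pvf1	ligand
PVR	Pvr	receptor
PVR	Pvf2	ligand
PVR	Pvf3	ligand
TGF-beta	dpp	ligand
TGF-beta	tkv	receptor
TGF-beta	put	receptor
TGF-beta	gbb	ligand
TGF-beta	sax	receptor
TGF-beta	scw	ligand
TGF-beta	daw	ligand
TGF-beta	babo	receptor
Insulin	Ilp2	ligand
Insulin	InR	receptor
Insulin	Ilp3	ligand
Insulin	Ilp5	ligand
Insulin	Ilp6	ligand
Toll	spz	ligand
Toll	Tl	receptor
Toll	spz3	ligand
Toll	Toll-7	receptor
Toll	spz5	ligand
Toll	Toll-6	receptor
Toll	spz6	ligand
Toll	Toll-8	receptor
Slit-Robo	sli	ligand
Slit-Robo	robo1	receptor
Slit-Robo	robo2	receptor
Slit-Robo	robo3	receptor
Adhesion	CadN	ligand
Adhesion	CadN	receptor
Adhesion	Fas2	ligand
Adhesion	Fas2	receptor
Adhesion	Fas3	ligand
Adhesion	Fas3	receptor
Adhesion	ed	ligand
Adhesion	ed	receptor
JAK-STAT	hop	core
JAK-STAT	Stat92E	core
Notch	Su(H)	core
Notch	mam	core
Hedgehog	ci	core
Hedgehog	cos	core
Wnt	arm	core
Wnt	dsh	core
EGFR	Ras85D	core
EGFR	rl	core
FGF	stumps	core
FGF	Ras85D	core
PVR	Ras85D	core
PVR	Akt1	core
TGF-beta	Mad	core
TGF-beta	Medea	core
Insulin	chico	core
Insulin	Akt1	core
Toll	Myd88	core
Toll	dl	core
Slit-Robo	ena	core
Slit-Robo	Abl	core
Adhesion	arm	core
Adhesion	baz	core
JAK-STAT	Socs36E	reporter
JAK-STAT	chinmo	reporter
JAK-STAT	dome	reporter
Notch	E(spl)m3-HLH	reporter
Notch	E(spl)mbeta-HLH	reporter
Notch	wg	reporter
Hedgehog	ptc	reporter
Hedgehog	dpp	reporter
Hedgehog	en	reporter
Wnt	nkd	reporter
Wnt	Notum	reporter
Wnt	fz3	reporter
EGFR	pnt	reporter
EGFR	aos	reporter
EGFR	sty	reporter
FGF	pnt	reporter
FGF	sty	reporter
PVR	pnt	reporter
PVR	aop	reporter
TGF-beta	Dad	reporter
TGF-beta	brk	reporter
Insulin	InR	reporter
Insulin	4E-BP	reporter
Insulin	foxo	reporter
Toll	Drs	reporter
Toll	Mtk	reporter
Toll	IM1	reporter
Slit-Robo	comm	reporter
Adhesion	shg	reporter
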