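# Closest-contact Calpha-Calpha gate residue pairs for MFS transporters.
# cytoplasmic gate: TM4-TM10; periplasmic gate: TM1-TM7.
# Residue numbering follows each transporter's deposited structure.
transporter	gate	resname_a	resid_a	resname_b	resid_b
EmrD	cytoplasmic	THR	119	PHE	311
EmrD	periplasmic	ALA	32	CYS	229
FucP	cytoplasmic	THR	143	SER	370
FucP	periplasmic	GLN	51	ILE	282
GlpT	cytoplasmic	TRP	138	ILE	368
GlpT	periplasmic	PRO	53	THR	278
LacY	cytoplasmic	GLU	126	CYS	333
LacY	periplasmic	ILE	32	ASN	245
NarU	cytoplasmic	MET	149	PHE	367
NarU	periplasmic	SER	54	ALA	273
NarK	cytoplasmic	MET	151	PHE	370
NarK	periplasmic	SER	56	ALA	275
PepT_So	cytoplasmic	SER	131	LEU	427
PepT_So	periplasmic	THR	36	SER	320
PepT_St	cytoplasmic	SER	130	GLY	407
PepT_St	periplasmic	ALA	34	SER	303
PiPT	cytoplasmic	ALA	154	ALA	439
PiPT	periplasmic	ASN	53	LEU	332
POT	cytoplasmic	ASN	138	GLY	420
POT	periplasmic	VAL	47	THR	314
XylE	cytoplasmic	MET	149	SER	396
XylE	periplasmic	SER	32	TYR	298
YajR	cytoplasmic	SER	125	SER	328
YajR	periplasmic	THR	37	PRO	236
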