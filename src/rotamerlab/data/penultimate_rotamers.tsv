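# Side-chain rotamer definitions: common-atom modal chi values from the
# Penultimate Rotamer Library (Lovell, Word, Richardson & Richardson,
# Proteins 40:389-408, 2000), in the published table order so that state
# IDs match the CCP4 rotamer-table numbering.
# ALA and GLY have no chi angles and are deliberately absent.
# Angles in degrees, interval (-180, 180].
residue_type	state_id	state_name	n_chi	chi1	chi2	chi3	chi4
ARG	1	ptp85	4	62	180	65	85
ARG	2	ptp180	4	62	180	65	-175
ARG	3	ptt85	4	62	180	180	85
ARG	4	ptt180	4	62	180	180	180
ARG	5	ptt-85	4	62	180	180	-85
ARG	6	ptm180	4	62	180	-65	175
ARG	7	ptm-85	4	62	180	-65	-85
ARG	8	tpp85	4	-177	65	65	85
ARG	9	tpp180	4	-177	65	65	-175
ARG	10	tpt85	4	-177	65	180	85
ARG	11	tpt180	4	-177	65	180	-175
ARG	12	ttp85	4	-177	180	65	85
ARG	13	ttp180	4	-177	180	65	-175
ARG	14	ttp-105	4	-177	180	65	-105
ARG	15	ttt85	4	-177	180	180	85
ARG	16	ttt180	4	-177	180	180	180
ARG	17	ttt-85	4	-177	180	180	-85
ARG	18	ttm105	4	-177	180	-65	105
ARG	19	ttm180	4	-177	180	-65	175
ARG	20	ttm-85	4	-177	180	-65	-85
ARG	21	mtp85	4	-67	180	65	85
ARG	22	mtp180	4	-67	180	65	-175
ARG	23	mtp-105	4	-67	180	65	-105
ARG	24	mtt85	4	-67	180	180	85
ARG	25	mtt180	4	-67	180	180	180
ARG	26	mtt-85	4	-67	180	180	-85
ARG	27	mtm105	4	-67	180	-65	105
ARG	28	mtm180	4	-67	180	-65	175
ARG	29	mtm-85	4	-67	180	-65	-85
ARG	30	mmt85	4	-62	-68	180	85
ARG	31	mmt180	4	-62	-68	180	180
ARG	32	mmt-85	4	-62	-68	180	-85
ARG	33	mmm180	4	-62	-68	-65	175
ARG	34	mmm-85	4	-62	-68	-65	-85
LYS	1	ptpt	4	62	180	68	180
LYS	2	pttp	4	62	180	180	65
LYS	3	pttt	4	62	180	180	180
LYS	4	pttm	4	62	180	180	-65
LYS	5	ptmt	4	62	180	-68	180
LYS	6	tptp	4	-177	68	180	65
LYS	7	tptt	4	-177	68	180	180
LYS	8	tptm	4	-177	68	180	-65
LYS	9	ttpp	4	-177	180	68	65
LYS	10	ttpt	4	-177	180	68	180
LYS	11	tttp	4	-177	180	180	65
LYS	12	tttt	4	-177	180	180	180
LYS	13	tttm	4	-177	180	180	-65
LYS	14	ttmt	4	-177	180	-68	180
LYS	15	ttmm	4	-177	180	-68	-65
LYS	16	mptt	4	-90	68	180	180
LYS	17	mtpp	4	-67	180	68	65
LYS	18	mtpt	4	-67	180	68	180
LYS	19	mttp	4	-67	180	180	65
LYS	20	mttt	4	-67	180	180	180
LYS	21	mttm	4	-67	180	180	-65
LYS	22	mtmt	4	-67	180	-68	180
LYS	23	mtmm	4	-67	180	-68	-65
LYS	24	mmtp	4	-62	-68	180	65
LYS	25	mmtt	4	-62	-68	180	180
LYS	26	mmtm	4	-62	-68	180	-65
LYS	27	mmmt	4	-62	-68	-68	180
MET	1	ptp	3	62	180	75
MET	2	ptm	3	62	180	-75
MET	3	tpp	3	-177	65	75
MET	4	tpt	3	-177	65	180
MET	5	ttp	3	-177	180	75
MET	6	ttt	3	-177	180	180
MET	7	ttm	3	-177	180	-75
MET	8	mtp	3	-67	180	75
MET	9	mtt	3	-67	180	180
MET	10	mtm	3	-67	180	-75
MET	11	mmp	3	-65	-65	103
MET	12	mmt	3	-65	-65	180
MET	13	mmm	3	-65	-65	-70
GLN	1	pt20	3	62	180	20
GLN	2	pm0	3	70	-75	0
GLN	3	tp-100	3	-177	65	-100
GLN	4	tp60	3	-177	65	60
GLN	5	tt0	3	-177	180	0
GLN	6	mp0	3	-65	85	0
GLN	7	mt-30	3	-67	180	-25
GLN	8	mm-40	3	-65	-65	-40
GLN	9	mm100	3	-65	-65	100
GLU	1	pt-20	3	62	180	-20
GLU	2	pm0	3	70	-80	0
GLU	3	tp10	3	-177	65	10
GLU	4	tt0	3	-177	180	0
GLU	5	tm-20	3	-177	-80	-25
GLU	6	mp0	3	-65	85	0
GLU	7	mt-10	3	-67	180	-10
GLU	8	mm-40	3	-65	-65	-40
ASP	1	p-10	2	62	-10
ASP	2	p30	2	62	30
ASP	3	t0	2	-177	0
ASP	4	t70	2	-177	65
ASP	5	m-20	2	-70	-15
ASN	1	p-10	2	62	-10
ASN	2	p30	2	62	30
ASN	3	t-20	2	-174	-20
ASN	4	t30	2	-177	30
ASN	5	m-20	2	-65	-20
ASN	6	m-80	2	-65	-75
ASN	7	m120	2	-65	120
ILE	1	pp	2	62	100
ILE	2	pt	2	62	170
ILE	3	tp	2	-177	66
ILE	4	tt	2	-177	165
ILE	5	mp	2	-65	100
ILE	6	mt	2	-65	170
ILE	7	mm	2	-57	-60
LEU	1	pp	2	62	80
LEU	2	tp	2	-177	65
LEU	3	tt	2	-172	145
LEU	4	mp	2	-85	65
LEU	5	mt	2	-65	175
HIS	1	p-80	2	62	-75
HIS	2	p80	2	62	80
HIS	3	t-160	2	-177	-165
HIS	4	t-80	2	-177	-80
HIS	5	t60	2	-177	60
HIS	6	m-70	2	-65	-70
HIS	7	m170	2	-65	165
HIS	8	m80	2	-65	80
TRP	1	p-90	2	62	-90
TRP	2	p90	2	62	90
TRP	3	t-105	2	-177	-105
TRP	4	t90	2	-177	90
TRP	5	m-90	2	-65	-90
TRP	6	m0	2	-65	-5
TRP	7	m95	2	-65	95
PHE	1	p90	2	62	90
PHE	2	t80	2	-177	80
PHE	3	m-85	2	-65	-85
PHE	4	m-30	2	-65	-30
TYR	1	p90	2	62	90
TYR	2	t80	2	-177	80
TYR	3	m-85	2	-65	-85
TYR	4	m-30	2	-65	-30
PRO	1	Cg_endo	1	30
PRO	2	Cg_exo	1	-30
SER	1	p	1	64
SER	2	t	1	178
SER	3	m	1	-65
THR	1	p	1	62
THR	2	t	1	-175
THR	3	m	1	-65
VAL	1	p	1	63
VAL	2	t	1	175
VAL	3	m	1	-60
CYS	1	p	1	62
CYS	2	t	1	-177
CYS	3	m	1	-65
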