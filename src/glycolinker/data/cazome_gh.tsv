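category	family	activity	VPI-5482	CMU13	CMU108	ATCC8483	CMU19	CMU33	CMU36	CMU103
cellulose/pectin-active	GH28	galacturonases	10	10	10	14	15	15	0	0
cellulose/pectin-active	GH95	alpha-L-fucosidase	5	5	5	7	**9**	**9**	4	4
cellulose/pectin-active	GH88	beta-glucouronyl hydrolase	4	3	3	8	6	6	1	1
cellulose/pectin-active	GH5	cellulase	0	**1**	**1**	5	**7**	**7**	1	1
cellulose/pectin-active	GH53	endo-1,4-beta-galactanase	1	1	1	1	**2**	**2**	0	0
cellulose/pectin-active	GH10	endo-1,4-beta-xylanase	0	0	0	7	3	3	0	0
cellulose/pectin-active	GH9	endoglucanase	0	0	0	1	1	1	0	0
cellulose/pectin-active	GH11	xylanase	0	0	0	0	0	0	0	0
cellulose/pectin-active	GH12	endoglucanase & xyloglucan hydrolysis	0	0	0	0	0	0	0	0
cellulose/pectin-active	GH26	beta-mannanase & xylanase	0	0	0	3	0	0	2	2
cellulose/pectin-active	GH44	endoglucanase	0	0	0	0	0	0	0	0
cellulose/pectin-active	GH45	endoglucanase	0	0	0	0	0	0	0	0
cellulose/pectin-active	GH48	endo-processive cellulases	0	0	0	0	0	0	0	0
cellulose/pectin-active	GH6	endoglucanase	0	0	0	0	0	0	0	0
cellulose/pectin-active	GH7	endoglucanase	0	0	0	0	0	0	0	0
cellulose/pectin-active	GH8	endo-xylanases	0	0	0	0	0	0	0	0
cell wall elongation	GH16	xyloglucanases & xyloglycosyltransferases	3	4	4	4	7	7	4	4
cell wall elongation	GH74	endoglucanases & xyloglucanases	0	1	1	0	0	0	1	1
cell wall elongation	GH17	1,3-beta-glucosidases	0	0	0	0	0	0	0	0
cell wall elongation	GH81	1,3-beta-glucanase	0	0	0	0	0	0	0	0
debranching	GH78	alpha-L-rhamnosidase	6	**9**	**9**	8	**9**	**9**	2	2
debranching	GH106	alpha-L-rhamnosidase	3	**4**	**4**	4	4	4	0	0
debranching	GH51	alpha-L-arabinofuranosidase	4	4	4	4	4	4	2	2
debranching	GH23	peptidoglycan lyase	3	**4**	3	3	3	3	3	3
debranching	GH33	trans-sialidase	2	2	2	5	5	5	4	4
debranching	GH146	beta-L-arabinofuranosidase	3	2	2	3	3	3	0	0
debranching	GH27	alpha-galactosidase	5	2	2	3	2	2	2	2
debranching	GH77	4-alpha-glucanotransferase	1	1	1	1	1	1	1	1
debranching	GH84	N-acetyl beta-glucosaminidase	1	1	1	0	0	0	1	1
debranching	GH67	alpha-glucuronidase	1	0	0	2	2	2	0	0
debranching	GH103	peptidoglycan lytic transglycosylase	0	0	0	0	0	0	0	0
debranching	GH54	alpha-L-arabinofuranosidase	0	0	0	0	0	0	0	0
debranching	GH62	alpha-L-arabinofuranosidase	0	0	0	0	0	0	0	0
oligosaccharide-degrading	GH2	beta-galactosidases and other beta-linked dimers	32	**34**	**34**	37	32	32	15	15
oligosaccharide-degrading	GH43	arabinases & xylosidases	34	33	33	35	**39**	**39**	10	10
oligosaccharide-degrading	GH92	alpha-1,2-mannosidase	23	**26**	**26**	18	**20**	**20**	8	8
oligosaccharide-degrading	GH20	beta-hexosaminidase	14	13	13	13	11	11	11	11
oligosaccharide-degrading	GH3	mainly beta-glucosidases	10	**11**	**11**	21	**23**	**23**	10	10
oligosaccharide-degrading	GH105	unsaturated rhamnogalacturonyl hydrolase	7	**9**	**9**	12	**15**	**15**	0	0
oligosaccharide-degrading	GH18	chitinase	12	9	9	8	**10**	**10**	2	2
oligosaccharide-degrading	GH97	glucoamylase, alpha-glucosidase, alpha-galactosidase	10	9	9	12	9	9	4	4
oligosaccharide-degrading	GH29	alpha-L-fucosidase	9	9	9	7	5	5	9	9
oligosaccharide-degrading	GH130	beta-1,4-mannosylglucose phosphorylase	4	**6**	**6**	8	6	6	2	2
oligosaccharide-degrading	GH31	alpha-glucosidase	6	6	6	12	6	6	4	4
oligosaccharide-degrading	GH35	beta-galactosidase	3	**4**	**4**	2	**5**	**5**	3	3
oligosaccharide-degrading	GH32	invertase, endo-inulinase	4	4	4	2	**3**	**3**	2	2
oligosaccharide-degrading	GH38	alpha-mannosidase	2	**4**	**4**	1	1	1	1	1
oligosaccharide-degrading	GH127	beta-L-arabinofuranosidase	3	3	3	1	**4**	**4**	5	5
oligosaccharide-degrading	GH13	alpha-amylase	8	2	2	5	2	2	2	2
oligosaccharide-degrading	GH141	alpha-L-fucosidase, xylanase	2	2	2	2	2	2	1	1
oligosaccharide-degrading	GH27	alpha-galactosidase	5	2	2	3	2	2	2	2
oligosaccharide-degrading	GH137	beta-L-arabinofuranosidase	1	2	2	1	1	1	1	1
oligosaccharide-degrading	GH42	beta-galactosidase	1	1	1	1	**3**	**3**	0	0
oligosaccharide-degrading	GH138	alpha-galacturonidase	1	1	1	1	1	1	0	0
oligosaccharide-degrading	GH139	alpha-2-O-Me-L-fucosidase	1	1	1	1	1	1	0	0
oligosaccharide-degrading	GH142	beta-L-arabinofuranosidase	1	1	1	1	1	1	1	1
oligosaccharide-degrading	GH143	2-keto-3-deoxy-D-lyxo-heptulosaric acid hydrolase	1	1	1	1	1	1	0	0
oligosaccharide-degrading	GH57	alpha-amylase	1	1	1	1	1	1	1	1
oligosaccharide-degrading	GH147	beta-galactosidase	0	0	0	1	**2**	**2**	0	0
oligosaccharide-degrading	GH1	beta-glucosidase and many other beta-linked dimers	0	0	0	0	0	0	0	0
oligosaccharide-degrading	GH39	beta-xylosidase	0	0	0	0	0	0	0	0
oligosaccharide-degrading	GH52	beta-xylosidase	0	0	0	0	0	0	0	0
oligosaccharide-degrading	GH94	cellobiose phosphorylase	0	0	0	0	0	0	0	0
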