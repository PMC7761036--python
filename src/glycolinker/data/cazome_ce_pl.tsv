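category	family	activity	VPI-5482	CMU13	CMU108	ATCC8483	CMU19	CMU33	CMU36	CMU103
polysaccharide lyases	PL22	oligogalacturonate/oligogalacturonide lyase	0	**3**	**3**	0	**3**	**3**	4	4
polysaccharide lyases	PL9	pectate lyase	2	2	2	3	1	1	0	0
polysaccharide lyases	PL10	pectate lyase	1	1	1	1	1	1	0	0
polysaccharide lyases	PL26	rhamnogalacturonan exolyase	1	1	1	1	1	1	0	0
polysaccharide lyases	PL1	pectate lyase	5	0	0	9	0	0	0	0
polysaccharide lyases	PL2	pectate lyase	0	0	0	0	0	0	0	0
polysaccharide lyases	PL3	pectate lyase	0	0	0	0	0	0	0	0
polysaccharide lyases	PL4	rhamnogalacturonan endolyase	0	0	0	0	0	0	0	0
carbohydrate esterases	CE6	acetyl xylan esterase	1	**11**	**11**	3	**17**	**17**	3	3
carbohydrate esterases	CE12	pectin acetylesterase	2	**5**	**5**	8	7	7	0	0
carbohydrate esterases	CE4	chitin deacetylase	1	**4**	**4**	2	**5**	**5**	2	2
carbohydrate esterases	CE8	pectin methylesterase	2	2	2	6	6	6	0	0
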