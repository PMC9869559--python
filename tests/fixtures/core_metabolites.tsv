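id	name	formula	charge
xyl__D_e	D-xylose (extracellular)	C5H10O5	0
co2_e	carbon dioxide (extracellular)	CO2	0
o2_e	dioxygen (extracellular)	O2	0
h2o_e	water (extracellular)	H2O	0
h_e	proton (extracellular)	H	1
pi_e	orthophosphate (extracellular)	HO4P	-2
btol_e	1,2,4-butanetriol (extracellular)	C4H10O3	0
glyclt_e	glycolate (extracellular)	C2H3O3	-1
xyl__D_c	D-xylose	C5H10O5	0
co2_c	carbon dioxide	CO2	0
o2_c	dioxygen	O2	0
h2o_c	water	H2O	0
h_c	proton	H	1
pi_c	orthophosphate	HO4P	-2
btol_c	1,2,4-butanetriol	C4H10O3	0
glyclt_c	glycolate	C2H3O3	-1
nadph_c	NADPH	C21H26N7O17P3	-4
xylt_c	xylitol	C5H12O5	0
nadp_c	NADP+	C21H25N7O17P3	-3
nad_c	NAD+	C21H26N7O14P2	-1
xylu__D_c	D-xylulose	C5H10O5	0
nadh_c	NADH	C21H27N7O14P2	-2
atp_c	ATP	C10H12N5O13P3	-4
xu5p__D_c	D-xylulose 5-phosphate	C5H9O8P	-2
adp_c	ADP	C10H12N5O10P2	-3
xylnl_c	D-xylono-1,4-lactone	C5H8O5	0
xyln_c	D-xylonate	C5H9O6	-1
kdx_c	2-keto-3-deoxy-D-xylonate	C5H7O5	-1
akgsa_c	alpha-ketoglutarate semialdehyde	C5H5O4	-1
akg_c	alpha-ketoglutarate	C5H6O5	0
pyr_c	pyruvate	C3H3O3	-1
gcald_c	glycolaldehyde	C2H4O2	0
dhbal_c	3,4-dihydroxybutanal	C4H8O3	0
g6p_c	D-glucose 6-phosphate	C6H11O9P	-2
f6p_c	D-fructose 6-phosphate	C6H11O9P	-2
fdp_c	D-fructose 1,6-bisphosphate	C6H10O12P2	-4
dhap_c	dihydroxyacetone phosphate	C3H5O6P	-2
g3p_c	glyceraldehyde 3-phosphate	C3H5O6P	-2
13dpg_c	1,3-bisphospho-D-glycerate	C3H4O10P2	-4
3pg_c	3-phospho-D-glycerate	C3H4O7P	-3
2pg_c	2-phospho-D-glycerate	C3H4O7P	-3
pep_c	phosphoenolpyruvate	C3H2O6P	-3
coa_c	coenzyme A	C21H32N7O16P3S	-4
accoa_c	acetyl-CoA	C23H34N7O17P3S	-4
oaa_c	oxaloacetate	C4H2O5	-2
6pgl_c	6-phospho-D-glucono-1,5-lactone	C6H9O9P	-2
6pgc_c	6-phospho-D-gluconate	C6H10O10P	-3
ru5p__D_c	D-ribulose 5-phosphate	C5H9O8P	-2
r5p_c	D-ribose 5-phosphate	C5H9O8P	-2
s7p_c	sedoheptulose 7-phosphate	C7H13O10P	-2
e4p_c	D-erythrose 4-phosphate	C4H7O7P	-2
cit_c	citrate	C6H5O7	-3
icit_c	isocitrate	C6H5O7	-3
succoa_c	succinyl-CoA	C25H35N7O19P3S	-5
succ_c	succinate	C4H4O4	-2
fad_c	FAD	C27H31N9O15P2	-2
fum_c	fumarate	C4H2O4	-2
fadh2_c	FADH2	C27H33N9O15P2	-2
mal__L_c	L-malate	C4H4O5	-2
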