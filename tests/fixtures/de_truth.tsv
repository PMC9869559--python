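gene_id	true_log2fc	planted	base_mean
Aopyc	0	none	190.5634001
BxxylX	2	up	812.5130963
Mtxyd1	2	up	262.711207
Mtxyl1	-2	down	869.9034851
aco1	0	none	413.2672569
adh1	0	none	596.1698809
aldA	0	none	129.5242799
cit1	2	up	240.5889003
eno1	2	up	582.8690281
etf1	0	none	258.6282962
fba1	0	none	124.8601498
fbp1	0	none	401.8545524
fum1	0	none	363.8699477
gnd1	0	none	479.393976
gpm1	0	none	253.3247165
idh1	0	none	306.5956038
idh2	0	none	297.5638728
kgd1	0	none	142.7001055
kgd2	0	none	260.3401657
kivD	0	none	509.7065416
ksaD	2	up	273.4025206
lpd1	0	none	597.1253968
lsc1	0	none	578.7235532
lsc2	0	none	253.9325187
mdh1	0	none	566.6165178
mdlC	0	none	505.4523961
ndi1	0	none	233.4201008
pck1	0	none	260.3032956
pda1	0	none	258.3493231
pdb1	0	none	116.7626027
pfk1	0	none	426.3800643
pgi1	0	none	397.2921186
pgk1	2	up	603.3163808
pho84	0	none	241.0827599
pyk1	0	none	120.6215323
rki1	0	none	198.2618596
rpe1	2	up	405.1062314
sdh1	0	none	170.8793882
sdh2	0	none	515.3687035
sol1	0	none	283.9733186
tal1	0	none	143.9575267
tdh1	0	none	280.2365186
tkl1	2	up	460.9464063
tkl2	0	none	103.372752
tpi1	0	none	545.1690542
xdh1	0	none	855.8224232
xks1	0	none	118.7294203
xtr1	0	none	305.4651315
xtr2	0	none	477.7679621
xylA	2	up	873.6116088
xylA_Ec	0	none	928.7411305
xylC	0	none	113.2460036
xylD	2	up	436.0165327
xylX	2	up	298.9902002
yagE	0	none	388.7684923
zwf1	0	none	757.5675388
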