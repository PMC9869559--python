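gene_id	log2FoldChange	padj	baseMean
Aopyc	0.2387976394	0.5268540103	187.6507081
BxxylX	1.63979458	4.798997344e-10	1877.753893
Mtxyd1	1.817897309	7.622565733e-12	670.639433
Mtxyl1	-1.770325392	6.363843847e-12	548.256508
aco1	-0.3103376331	0.4509338318	454.5386188
adh1	-0.5770586236	0.1269517967	664.0438282
aldA	-0.1601471977	0.7172388529	96.05634629
cit1	2.256894081	7.820043828e-18	570.7796425
eno1	2.410604	3.878352431e-19	1362.37832
etf1	-0.4787180239	0.1936997602	200.8854447
fba1	0.08081633618	0.8566903265	105.5090695
fbp1	-0.05269542608	0.9290566815	346.3268432
fum1	-0.4516689577	0.1686287201	386.8367976
gnd1	-0.5759774613	0.05893290402	388.3936251
gpm1	-0.05054127555	0.8566903265	291.5239954
idh1	-0.7285026985	0.02369429602	343.4877981
idh2	-0.08424883616	0.8566903265	235.3227933
kgd1	0.3571116453	0.2786980486	124.7296278
kgd2	-0.1586019016	0.7172388529	276.2016192
kivD	-0.3122655438	0.4509338318	466.2237053
ksaD	1.948196521	2.270107607e-13	553.0948295
lpd1	-0.4189639299	0.2401737341	453.1588214
lsc1	-0.07317295121	0.8829079836	539.5810799
lsc2	-0.163168565	0.754826685	250.2517125
mdh1	-0.07568240585	0.8849668859	546.4832786
mdlC	0.2287361898	0.484542006	408.7413221
ndi1	0.1043191677	0.9290566815	218.5060767
pck1	-0.1938013084	0.6116182168	282.7094435
pda1	0.5548075286	0.1281882687	193.3328105
pdb1	-0.6404033481	0.1083678563	107.8883659
pfk1	-0.406798671	0.2574734377	497.5027144
pgi1	0.423621188	0.24734462	310.6190302
pgk1	2.157647092	3.117335092e-17	1639.925214
pho84	0.2976193262	0.4533861043	170.9726691
pyk1	-0.04607718651	0.9290566815	135.8762609
rki1	-0.3003272746	0.4509338318	175.1819755
rpe1	2.056640099	1.574885199e-14	1019.82093
sdh1	-0.01108227718	0.9937437082	160.9101368
sdh2	-0.18474795	0.6881954641	420.2203387
sol1	-0.04494345848	0.9290566815	269.6873278
tal1	-0.4532877919	0.1936997602	136.2833589
tdh1	0.2139211046	0.6116182168	178.861725
tkl1	1.996728701	2.270107607e-13	1170.051221
tkl2	-0.3178699717	0.4499104651	91.07987736
tpi1	-0.1867988657	0.754826685	495.9231694
xdh1	-0.3407366151	0.4509338318	705.6691236
xks1	-0.1381644647	0.754826685	121.054413
xtr1	0.478919012	0.1407512424	218.9229267
xtr2	-0.5797612575	0.06978634118	458.7696948
xylA	1.933608492	2.504997415e-13	1835.944003
xylA_Ec	0.08435052029	0.8566903265	884.9903657
xylC	-0.03102182414	0.9814702319	98.1803877
xylD	1.805766239	6.363843847e-12	1085.847059
xylX	1.95481755	2.628820298e-13	634.7019
yagE	-0.2245582412	0.6116182168	398.6345634
zwf1	-0.03410002879	0.9449225857	760.3667843
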