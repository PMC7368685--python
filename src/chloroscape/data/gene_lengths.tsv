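# gene	typical aligned CDS length (bp, divisible by 3), angiosperm plastome
psaA	2253
psaB	2205
psaC	246
psaI	111
psaJ	135
psbA	1062
psbB	1527
psbC	1422
psbD	1062
psbE	252
psbF	120
psbH	222
psbI	111
psbJ	123
psbL	117
psbM	105
psbN	132
psbT	108
psbZ	189
petA	963
petB	648
petD	483
petG	114
petF	366
petN	90
atpA	1524
atpB	1497
atpE	402
atpF	555
atpH	246
atpI	744
rbcL	1428
rpoA	1014
rpoB	3213
rpoC1	2046
rpoC2	4200
rpl2	825
rpl14	369
rpl16	408
rpl20	354
rpl22	450
rpl23	282
rpl32	174
rpl33	201
rpl36	114
rps2	711
rps3	657
rps4	606
rps7	468
rps8	405
rps11	417
rps12	372
rps14	303
rps15	273
rps18	306
rps19	279
ndhA	1092
ndhB	1533
ndhC	363
ndhD	1503
ndhE	306
ndhF	2220
ndhG	531
ndhH	1182
ndhI	504
ndhJ	477
ndhK	678
ycf1	5502
ycf2	6900
ycf3	507
ycf4	555
accD	1500
clpP	591
ccsA	960
cemA	690
matK	1530
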