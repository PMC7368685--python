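# gene	region (canonical angiosperm plastome layout; config-driven, genes
# spanning IR boundaries are assigned to the region holding most of the CDS)
psaA	LSC
psaB	LSC
psaC	SSC
psaI	LSC
psaJ	LSC
psbA	LSC
psbB	LSC
psbC	LSC
psbD	LSC
psbE	LSC
psbF	LSC
psbH	LSC
psbI	LSC
psbJ	LSC
psbL	LSC
psbM	LSC
psbN	LSC
psbT	LSC
psbZ	LSC
petA	LSC
petB	LSC
petD	LSC
petG	LSC
petF	LSC
petN	LSC
atpA	LSC
atpB	LSC
atpE	LSC
atpF	LSC
atpH	LSC
atpI	LSC
rbcL	LSC
rpoA	LSC
rpoB	LSC
rpoC1	LSC
rpoC2	LSC
rpl2	IR
rpl14	LSC
rpl16	LSC
rpl20	LSC
rpl22	LSC
rpl23	IR
rpl32	SSC
rpl33	LSC
rpl36	LSC
rps2	LSC
rps3	LSC
rps4	LSC
rps7	IR
rps8	LSC
rps11	LSC
rps12	IR
rps14	LSC
rps15	SSC
rps18	LSC
rps19	LSC
ndhA	SSC
ndhB	IR
ndhC	LSC
ndhD	SSC
ndhE	SSC
ndhF	SSC
ndhG	SSC
ndhH	SSC
ndhI	SSC
ndhJ	LSC
ndhK	LSC
ycf1	SSC
ycf2	IR
ycf3	LSC
ycf4	LSC
accD	LSC
clpP	LSC
ccsA	SSC
cemA	LSC
matK	LSC
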