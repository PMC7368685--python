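# gene	functional_group
psaA	PSA
psaB	PSA
psaC	PSA
psaI	PSA
psaJ	PSA
psbA	PSB
psbB	PSB
psbC	PSB
psbD	PSB
psbE	PSB
psbF	PSB
psbH	PSB
psbI	PSB
psbJ	PSB
psbL	PSB
psbM	PSB
psbN	PSB
psbT	PSB
psbZ	PSB
petA	PET
petB	PET
petD	PET
petG	PET
petF	PET
petN	PET
atpA	ATP
atpB	ATP
atpE	ATP
atpF	ATP
atpH	ATP
atpI	ATP
rbcL	Rubisco
rpoA	RPO
rpoB	RPO
rpoC1	RPO
rpoC2	RPO
rpl2	RPL
rpl14	RPL
rpl16	RPL
rpl20	RPL
rpl22	RPL
rpl23	RPL
rpl32	RPL
rpl33	RPL
rpl36	RPL
rps2	RPS
rps3	RPS
rps4	RPS
rps7	RPS
rps8	RPS
rps11	RPS
rps12	RPS
rps14	RPS
rps15	RPS
rps18	RPS
rps19	RPS
ndhA	NDH
ndhB	NDH
ndhC	NDH
ndhD	NDH
ndhE	NDH
ndhF	NDH
ndhG	NDH
ndhH	NDH
ndhI	NDH
ndhJ	NDH
ndhK	NDH
ycf1	OG
ycf2	OG
ycf3	OG
ycf4	OG
accD	OG
clpP	OG
ccsA	OG
cemA	OG
matK	OG
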