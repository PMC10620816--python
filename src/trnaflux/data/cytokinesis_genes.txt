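# Illustrative 80-gene cytokinesis-related list (NON-AUTHORITATIVE).
# Hand-assembled from well-known cytokinesis machinery (central spindle,
# contractile ring, abscission/ESCRT) purely as a demonstration fixture;
# supply your own curated list for real analyses.
ANLN
ECT2
RACGAP1
KIF23
KIF4A
KIF20A
KIF14
PRC1
PLK1
AURKA
AURKB
INCENP
CDCA8
BIRC5
CIT
ROCK1
ROCK2
RHOA
MYH9
MYH10
MYL9
ACTR2
ACTR3
ARPC1B
DIAPH1
DIAPH3
FMNL3
SPTBN1
SEPTIN1
SEPTIN2
SEPTIN3
SEPTIN4
SEPTIN5
SEPTIN6
SEPTIN7
SEPTIN8
SEPTIN9
SEPTIN10
SEPTIN11
SEPTIN12
CEP55
PDCD6IP
TSG101
CHMP1A
CHMP1B
CHMP2A
CHMP2B
CHMP3
CHMP4A
CHMP4B
CHMP4C
CHMP5
CHMP6
CHMP7
IST1
VPS4A
VPS4B
SPAST
TTC19
TEX14
NUSAP1
TPX2
CENPE
CDC14A
CDC14B
CDC42
MYLK
PAK1
LIMK1
CFL1
CAPZA1
TLN1
VIM
PLK4
CDK1
CCNB1
CCNB2
FZR1
UBE2C
ESPL1
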