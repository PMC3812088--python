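# Continent-island version of the African divergence model: sampled
# San (0) and Yoruba (1) islands receive migrants from their continents
# (2=San continent, 3=Yoruba continent); the continents exchanged a
# pulse of gene flow at TA and migrated continuously at rates MSY/MYS
# between TEY (start of the Yoruban expansion, ancestral size NDY) and
# their divergence at TDS (ancestral African size NAFR). Deme 4 is the
# Denisova calibration genome (divergence fixed at 16000 generations).
[populations]
0 30000 0 12
1 30000 0 12
2 NCS 0 0
3 NCY 0 0
4 10000 0 2

[migration]
matrix 0
0 0 MS 0 0
0 0 0 MY 0
0 0 0 0 0
0 0 0 0 0
0 0 0 0 0
matrix 1
0 0 MS 0 0
0 0 0 MY 0
0 0 0 MSY 0
0 0 MYS 0 0
0 0 0 0 0
matrix 2
0 0 MS 0 0
0 0 MY 0 0
0 0 0 0 0
0 0 0 0 0
0 0 0 0 0

[events]
TA  2 3 AYS . . .
TA  3 2 ASY . . .
TEY 3 3 0 NDY . 1
TDS 3 2 1 NAFR . 2
16000 0 4 1 . . .
16000 1 4 1 . . .
16000 2 4 1 NANC . .
16000 3 4 1 . . .

[parameters]
NCS  size 1e3 1e6 log10 free
NCY  size 1e3 1e6 log10 free
NDY  size 50  1e4 log10 free
NAFR size 100 1e5 log10 free
NANC size .   .   .     fixed=10000
MS   rate 1e-6 1e-2 log10 free
MY   rate 1e-6 1e-2 log10 free
MSY  rate 1e-7 1e-3 log10 free
MYS  rate 1e-7 1e-3 log10 free
AYS  proportion 0 0.5 linear free
ASY  proportion 0 0.5 linear free
TA   time 10 100 log10 free
DTEY time 10 1000 log10 free
DTDS time 100 12000 log10 free

[derived]
TEY = TA + DTEY
TDS = TEY + DTDS
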