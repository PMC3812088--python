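# Continent-island version of the four-population human model: sampled
# demes 0=ASW, 1=CEU, 2=LWK, 3=YRI are islands formed 100 generations
# ago; deme 4 is the European continent (source of CEU migrants and of
# the ASW European contribution AE), deme 5 the Niger-Congo continent
# (source of LWK/YRI migrants and of the rest of ASW), deme 6 the
# ancestral African population. Both continents passed through 100-
# generation bottlenecks (NBEUR, NBNC) when they diverged from the
# African population (at the fixed calibration time 2000 and at TNC).
[populations]
0 NASW 0 10
1 NCEU 0 18
2 NLWK 0 8
3 NYRI 0 18
4 NEUR 0 0
5 NNC  0 0
6 NAFR 0 0

[migration]
matrix 0
0 0 0 0 0 0 0
0 0 0 0 MC 0 0
0 0 0 0 0 ML 0
0 0 0 0 0 MY 0
0 0 0 0 0 0 0
0 0 0 0 0 0 0
0 0 0 0 0 0 0
matrix 1
0 0 0 0 0 0 0
0 0 0 0 0 0 0
0 0 0 0 0 0 0
0 0 0 0 0 0 0
0 0 0 0 0 0 0
0 0 0 0 0 0 0
0 0 0 0 0 0 0

[events]
16    0 4 AE . . .
16    0 5 1  . . .
100   1 4 1 . . .
100   2 5 1 . . .
100   3 5 1 . . 1
TNCB  5 5 0 NBNC . .
TNC   5 6 1 . . .
1900  4 4 0 NBEUR . .
2000  4 6 1 NAFR . .
TBOT  6 6 0 NANC . .

[parameters]
NASW  size 100 1e6 log10 free
NCEU  size 100 1e6 log10 free
NLWK  size 100 1e6 log10 free
NYRI  size 100 1e6 log10 free
NEUR  size 100 1e6 log10 free
NNC   size 100 1e6 log10 free
NAFR  size 100 1e6 log10 free
NBNC  size 100 1e6 log10 free
NBEUR size 100 1e6 log10 free
NANC  size 100 1e6 log10 free
MC    rate 1e-7 1e-2 log10 free
ML    rate 1e-7 1e-2 log10 free
MY    rate 1e-7 1e-2 log10 free
AE    proportion 0 1 linear free
TNCB  time 110 1700 log10 free
DTBOT time 10 1e5 log10 free

[derived]
TNC  = TNCB + 100
TBOT = 2100 + DTBOT
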