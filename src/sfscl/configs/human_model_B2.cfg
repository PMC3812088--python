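# Model B1 plus a possible admixture of the Luhya population from an
# unsampled (East-African) deme 7, contributing a proportion AEA to the
# initial LWK island 100 generations ago; the East-African population
# diverged from the ancestral African population TEA generations ago.
[populations]
0 NASW 0 10
1 NCEU 0 18
2 NLWK 0 8
3 NYRI 0 18
4 NEUR 0 0
5 NNC  0 0
6 NAFR 0 0
7 NEA  0 0

[migration]
matrix 0
0 0 0 0 0 0 0 0
0 0 0 0 MC 0 0 0
0 0 0 0 0 ML 0 0
0 0 0 0 0 MY 0 0
0 0 0 0 0 0 0 0
0 0 0 0 0 0 0 0
0 0 0 0 0 0 0 0
0 0 0 0 0 0 0 0
matrix 1
0 0 0 0 0 0 0 0
0 0 0 0 0 0 0 0
0 0 0 0 0 0 0 0
0 0 0 0 0 0 0 0
0 0 0 0 0 0 0 0
0 0 0 0 0 0 0 0
0 0 0 0 0 0 0 0
0 0 0 0 0 0 0 0

[events]
16    0 4 AE . . .
16    0 5 1  . . .
100   2 7 AEA . . .
100   1 4 1 . . .
100   2 5 1 . . .
100   3 5 1 . . 1
TNCB  5 5 0 NBNC . .
TNC   5 6 1 . . .
1900  4 4 0 NBEUR . .
2000  4 6 1 NAFR . .
TEA   7 6 1 . . .
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
NEA   size 100 1e6 log10 free
MC    rate 1e-7 1e-2 log10 free
ML    rate 1e-7 1e-2 log10 free
MY    rate 1e-7 1e-2 log10 free
AE    proportion 0 1 linear free
AEA   proportion 0 1 linear free
TNCB  time 110 1700 log10 free
TEA   time 150 8000 log10 free
DTBOT time 10 1e5 log10 free

[derived]
TNC  = TNCB + 100
TBOT = 2100 + DTBOT
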