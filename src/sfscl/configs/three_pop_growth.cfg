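# Three-population divergence with growth, migration and a founding
# bottleneck: deme 0 constant (African-like), demes 1 and 2 grow to a
# known current size of 1e6 diploids at rate R after splitting at TSPLIT
# from a founder of size NB; the founder diverged from deme 0 at TDIV.
# Defaults are user-editable placeholders, not published values.
[populations]
0 NAFR 0 20
1 1e6  R 20
2 1e6  R 20

[migration]
matrix 0
0 M M
M 0 M
M M 0
matrix 1
0 0 0
0 0 0
0 0 0

[events]
TSPLIT 2 2 0 . 0 .
TSPLIT 2 1 1 NB 0 .
TDIV   1 0 1 NANC 0 1
TDIV   2 0 1 . . .

[parameters]
NAFR   size 100  1e6  log10 free
NB     size 10   1e5  log10 free
TSPLIT time 10   1e4  log10 free
DTDIV  time 10   1e5  log10 free
M      rate 1e-7 1e-3 log10 free
R      rate 1e-4 1e-2 log10 free
NANC   size .    .    .     fixed=10000

[derived]
TDIV = TSPLIT + DTDIV
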