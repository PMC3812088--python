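# Two successive continent-island systems: ten sampled islands of 500
# diploids (demes 0-9), an older continent (deme 10) feeding islands 0-4
# and a younger continent (deme 11, stemming from the older system at
# TCI2) feeding islands 5-9. Backward, island lineages migrate into their
# continent at rates M1/M2; after the continents fuse, all islands feed
# deme 10. Fit with the pairwise-product composite likelihood.
# Defaults are user-editable placeholders, not published values.
[populations]
0 500 0 4
1 500 0 4
2 500 0 4
3 500 0 4
4 500 0 4
5 500 0 4
6 500 0 4
7 500 0 4
8 500 0 4
9 500 0 4
10 NC1 0 0
11 NC2 0 0

[migration]
matrix 0
0 0 0 0 0 0 0 0 0 0 M1 0
0 0 0 0 0 0 0 0 0 0 M1 0
0 0 0 0 0 0 0 0 0 0 M1 0
0 0 0 0 0 0 0 0 0 0 M1 0
0 0 0 0 0 0 0 0 0 0 M1 0
0 0 0 0 0 0 0 0 0 0 0 M2
0 0 0 0 0 0 0 0 0 0 0 M2
0 0 0 0 0 0 0 0 0 0 0 M2
0 0 0 0 0 0 0 0 0 0 0 M2
0 0 0 0 0 0 0 0 0 0 0 M2
0 0 0 0 0 0 0 0 0 0 0 0
0 0 0 0 0 0 0 0 0 0 0 0
matrix 1
0 0 0 0 0 0 0 0 0 0 M1 0
0 0 0 0 0 0 0 0 0 0 M1 0
0 0 0 0 0 0 0 0 0 0 M1 0
0 0 0 0 0 0 0 0 0 0 M1 0
0 0 0 0 0 0 0 0 0 0 M1 0
0 0 0 0 0 0 0 0 0 0 M2 0
0 0 0 0 0 0 0 0 0 0 M2 0
0 0 0 0 0 0 0 0 0 0 M2 0
0 0 0 0 0 0 0 0 0 0 M2 0
0 0 0 0 0 0 0 0 0 0 M2 0
0 0 0 0 0 0 0 0 0 0 0 0
0 0 0 0 0 0 0 0 0 0 0 0

[events]
TCI2 11 10 1 . . 1
TCI1 10 10 0 NANC . .

[parameters]
M1   rate 1e-6 1e-1 log10 free
M2   rate 1e-6 1e-1 log10 free
NC1  size 100  1e6  log10 free
NC2  size 100  1e6  log10 free
TCI2 time 10   1e4  log10 free
DT1  time 10   1e5  log10 free
NANC size .    .    .     fixed=10000

[derived]
TCI1 = TCI2 + DT1
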