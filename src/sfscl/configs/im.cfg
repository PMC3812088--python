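# Isolation with asymmetric migration: two demes exchanging migrants at
# backward rates M12 (deme 0 -> 1) and M21 since their divergence at TDIV.
# Defaults are user-editable placeholders, not published values.
[populations]
0 N1 0 20
1 N2 0 30

[migration]
matrix 0
0   M12
M21 0
matrix 1
0 0
0 0

[events]
TDIV 1 0 1 NANC . 1

[parameters]
N1   size 10   1e5  log10 free
N2   size 10   1e5  log10 free
TDIV time 10   1e5  log10 free
M12  rate 1e-7 1e-3 log10 free
M21  rate 1e-7 1e-3 log10 free
NANC size .    .    .     fixed=10000
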