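# Two populations of sizes N1, N2 that diverged TDIV generations ago from
# an ancestral population of (fixed) size NANC, without migration.
# Benchmark truth (gene-copy units 2N1=10000, 2N2=1000, 2NA=10000):
# N1=5000, N2=500, NANC=5000, TDIV = 0.1 x 2NA = 1000.
[populations]
0 N1 0 20
1 N2 0 30

[events]
TDIV 1 0 1 NANC . .

[parameters]
N1   size 10 1e5 log10 free
N2   size 10 1e5 log10 free
TDIV time 10 1e5 log10 free
NANC size .  .   .     fixed=5000
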