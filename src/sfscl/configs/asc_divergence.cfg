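# Divergence model for SNP-chip data ascertained as heterozygous sites in
# one individual of deme 0 (run with --asc-pop 0 -0). Defaults are
# user-editable placeholders, not published values.
[populations]
0 N1 0 20
1 N2 0 20

[events]
TDIV 1 0 1 NANC . .

[parameters]
N1   size 100 1e6 log10 free
N2   size 100 1e6 log10 free
TDIV time 10  1e5 log10 free
NANC size .   .   .     fixed=10000
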