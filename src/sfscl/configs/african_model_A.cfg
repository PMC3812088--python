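# Divergence of two African populations typed on an ascertained SNP
# panel (run with --asc-pop 0 or 1, and -0): 0=San, 1=Yoruba, 2=Denisova
# (one archaic genome used to calibrate the time scale: its divergence
# from the ancestral human population is fixed at 16000 generations).
# San and Yoruba expanded to NSAN/NYOR from ancestral sizes NAS/NAY at
# TES/TEY, diverged at TDIV, and exchanged a single bidirectional pulse
# of gene flow at TA (proportions AYS, ASY).
[populations]
0 NSAN 0 12
1 NYOR 0 12
2 10000 0 2

[events]
TA   0 1 AYS . . .
TA   1 0 ASY . . .
TES  0 0 0 NAS . .
TEY  1 1 0 NAY . .
TDIV 1 0 1 NAFR . .
16000 0 2 1 NANC . .
16000 1 2 1 . . .

[parameters]
NSAN size 1e3 1e6 log10 free
NYOR size 1e3 1e6 log10 free
NAS  size 100 1e5 log10 free
NAY  size 100 1e5 log10 free
NAFR size 100 1e5 log10 free
NANC size .   .   .     fixed=10000
AYS  proportion 0 0.5 linear free
ASY  proportion 0 0.5 linear free
TA   time 10  1000 log10 free
TES  time 10  2000 log10 free
TEY  time 10  2000 log10 free
TDIV time 100 12000 log10 free
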