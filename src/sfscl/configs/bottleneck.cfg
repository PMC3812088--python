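# Single population that passed through a bottleneck: current size NCUR,
# reduced to NBOT between TBOT and TBOT+100 generations ago, ancestral
# size NANC (fixed). Benchmark truth: NCUR=10000, NBOT=100, TBOT=1000.
[populations]
# id size growth sample_size
0 NCUR 0 20

[events]
# time source sink proportion new_size new_growth matrix
TBOT    0 0 0 NBOT . .
TBOTEND 0 0 0 NANC . .

[parameters]
# name kind lo hi scale status
NCUR size 10 1e5 log10 free
NBOT size 10 1e5 log10 free
TBOT time 10 1e5 log10 free
NANC size .  .   .     fixed=10000

[derived]
TBOTEND = TBOT + 100
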