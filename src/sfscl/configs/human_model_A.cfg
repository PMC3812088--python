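# Four sampled human populations: 0=ASW (African-American), 1=CEU
# (European), 2=LWK (Luhya), 3=YRI (Yoruba). The ASW population was
# founded 16 generations ago with contributions AE from CEU and AL from
# LWK (remainder from YRI). LWK and YRI diverged TNC generations ago;
# the European lineage split from the African 2000 generations ago
# (calibration); the African ancestor passed through a bottleneck of
# size NBOT for 100 generations starting TBOT, with ancestral size NANC.
# Deme 3 carries the ancestral African population backward in time.
[populations]
0 NASW 0 10
1 NCEU 0 18
2 NLWK 0 8
3 NYRI 0 18

[events]
# ASW admixture pulses (processed in file order at t=16)
16   0 1 AE . . .
16   0 2 AL . . .
16   0 3 1  . . .
TNC  2 3 1 . . .
2000 1 3 1 NAFR . .
TBOT 3 3 0 NBOT . .
TBOTE 3 3 0 NANC . .

[parameters]
NASW size 100 1e6 log10 free
NCEU size 100 1e6 log10 free
NLWK size 100 1e6 log10 free
NYRI size 100 1e6 log10 free
NAFR size 100 1e6 log10 free
NBOT size 100 1e6 log10 free
NANC size 100 1e6 log10 free
AE proportion 0 1 linear free
AL proportion 0 1 linear free
TNC  time 20 1900 log10 free
DTBOT time 10 1e5 log10 free

[derived]
TBOT = 2100 + DTBOT
TBOTE = TBOT + 100
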