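# synthetic solvent-accessibility mask
# version: synthetic-mask-1.0
locus	positions
DQB1	3,9,13,14,26,28,30,37,38,45,46,52,53,55,57,66,67,70,71,74,77,84,85,86,87
A	2,4,5,7,9,11
B	2,4,5,7,9,11
C	2,4,5,7,9,11
DRB1	2,4,5,7,9,11
DRB3	2,4,5,7,9,11
DQA1	2,4,5,7,9,11
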