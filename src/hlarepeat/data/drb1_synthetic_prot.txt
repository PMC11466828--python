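# synthetic DRB1 protein alignment (mature numbering, position 1 first column)
# dialect: first allele line is the reference; '-' = identical to reference, '*' = unknown
DRB1*01:01 WMWVPLYWCVPN
DRB1*04:01 -I-W--G-----
DRB1*07:01 ----V---H---
DRB1*11:01 -P-W--G-H-R-
DRB1*13:01 ---GE-G-G---
DRB1*15:01 -P-GV---G-R-
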