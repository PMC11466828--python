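# synthetic C protein alignment (mature numbering, position 1 first column)
# dialect: first allele line is the reference; '-' = identical to reference, '*' = unknown
C*01:02 EWKKLSLEIWVE
C*02:02 -I-RV-Y---A-
C*03:03 -I-RV---M-P-
C*04:01 -V-R----M---
C*06:02 ----V---T-P-
C*07:01 -V-CV-G-M-A-
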