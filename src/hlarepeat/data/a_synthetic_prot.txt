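# synthetic A protein alignment (mature numbering, position 1 first column)
# dialect: first allele line is the reference; '-' = identical to reference, '*' = unknown
A*01:01 EFRCCVPGPTFV
A*02:01 ---T----T-R-
A*03:01 -W-YF-S-V---
A*11:01 ---YD-------
A*24:02 -E-YD-S---H-
A*26:01 ---TF---*---
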