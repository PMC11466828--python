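# synthetic DQA1 protein alignment (mature numbering, position 1 first column)
# dialect: first allele line is the reference; '-' = identical to reference, '*' = unknown
DQA1*01:01 LLDCGCVWCCVR
DQA1*03:01 -S-A--------
DQA1*05:01 ---VK---P-W-
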