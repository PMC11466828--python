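# synthetic DRB3 protein alignment (mature numbering, position 1 first column)
# dialect: first allele line is the reference; '-' = identical to reference, '*' = unknown
DRB3*01:01 VMVQVAQEDPCH
DRB3*02:02 -H--M-----T-
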