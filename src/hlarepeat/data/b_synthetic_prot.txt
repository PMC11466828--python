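# synthetic B protein alignment (mature numbering, position 1 first column)
# dialect: first allele line is the reference; '-' = identical to reference, '*' = unknown
B*07:02 RPRFRLCQLLGL
B*08:01 -Y-GL-A-S---
B*27:05 -Y-T--G-S---
B*35:01 -Y--P-A-S---
B*44:02 -W----A-S-A-
B*51:01 -Y-TP-A-Q---
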