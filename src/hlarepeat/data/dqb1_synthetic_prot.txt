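# synthetic DQB1 protein alignment (mature numbering, position 1 first column)
# dialect: first allele line is the reference; '-' = identical to reference, '*' = unknown
DQB1*02:01 QSWSKCLCYVGYGMLKRLYFPISKREHTVYMFTQGVIVGFPPWCGKWQNFHPQWPPASMSPLDGNEVVCRKFQAMIREHNLTHQLEL
DQB1*02:02 -----------------------------------------------------------------------------------L---
DQB1*03:01 -------------L-----------Y----------D-------E-----------D------------GT--S--T-------VG-
DQB1*03:02 ------------AL-----------L----------YA------E-------------------------T-----T-------VG-
DQB1*03:03 ------------AL-----------L----------D-------E-----------D------------GT-----T-------V--
DQB1*04:01 --------F---A------------L-S--------Y-----------------R-D------------GT--E--T--------G-
DQB1*04:02 --------F----------------L----------Y-----------------R-D------------GA-----T--------G-
DQB1*05:01 -----------------------------H------D--------------L--R-D------------GT---------------F
DQB1*06:02 --------F---A------------G-----------A--------------L-R-D--------VM--GA-----T--------GF
DQB1*06:03 --------F----------------G-----------A----------------R-D--------V---GA-----T--------GF
DQB1*06:04 --------F----------------G-----------A----------------R----------VM--GA-----T-------VGF
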