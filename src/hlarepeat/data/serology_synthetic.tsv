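# synthetic serology map (WHO-style split designations)
# version: synthetic-serology-1.0
allele	split	broad
A*01:01	A1	A1
A*02:01	A2	A2
A*03:01	A3	A3
A*11:01	A11	A11
A*24:02	A24	A9
A*26:01	A26	A10
B*07:02	B7	B7
B*08:01	B8	B8
B*27:05	B27	B27
B*35:01	B35	B35
B*44:02	B44	B12
B*51:01	B51	B5
C*01:02	Cw1	Cw1
C*02:02	Cw2	Cw2
C*03:03	Cw3	Cw3
C*04:01	Cw4	Cw4
C*06:02	Cw6	Cw6
C*07:01	Cw7	Cw7
DRB1*01:01	DR1	DR1
DRB1*04:01	DR4	DR4
DRB1*07:01	DR7	DR7
DRB1*11:01	DR11	DR5
DRB1*13:01	DR13	DR6
DRB1*15:01	DR15	DR2
DRB3*01:01	DR52	DR52
DRB3*02:02	DR52	DR52
DQA1*01:01	DQA1	DQA1
DQA1*03:01	DQA3	DQA3
DQA1*05:01	DQA5	DQA5
DQB1*02:01	DQ2	DQ2
DQB1*02:02	DQ2	DQ2
DQB1*03:01	DQ7	DQ3
DQB1*03:02	DQ8	DQ3
DQB1*03:03	DQ9	DQ3
DQB1*04:01	DQ4	DQ4
DQB1*04:02	DQ4	DQ4
DQB1*05:01	DQ5	DQ1
DQB1*06:02	DQ6	DQ1
DQB1*06:03	DQ6	DQ1
DQB1*06:04	DQ6	DQ1
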