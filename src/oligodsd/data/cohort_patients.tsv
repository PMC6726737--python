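patient_id	karyotype	mamld1_variant
1	46,XY	NM_005491:c.1514T>C
2	46,XY	NM_005491:c.1508C>A
3	46,XY	NM_005491:c.2190G>A
4	46,XY	NM_005491:c.1041C>A
5	46,XY	NM_005491:c.1041C>A
6	46,XY	NM_005491:c.2170C>G
7	46,XY	NM_005491:c.1503_1504dupCAGCAG
8	46,XX	NM_005491:c.*126C>MIT
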