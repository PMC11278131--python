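tissue,I1,I2,I3,I4,I5,I6,I7,I8,I9,I10,I11,I12,I13,I14,I15,I16,I17,I18,I19,I20
BLADDER,P,P,F,P,P,P,P,P,F,P,P,P,P,P,P,P,F,P,P,P
CERVIX,P,P,F,P,P,P,P,P,P,P,P,P,P,P,P,P,P,P,P,P
KIDNEY,F,P,P,P,F,P,P,P,P,F,F,F,P,F,P,P,P,P,P,P
OVARY,P,F,F,P,P,F,P,F,P,P,F,F,F,P,P,P,F,F,F,F
PROSTATE,P,P,P,P,P,P,P,P,F,P,P,F,P,P,P,P,P,P,F,P
TESTIS,P,P,P,P,P,P,P,P,P,P,P,P,P,P,P,P,P,P,P,P
UTERUS,P,P,P,P,P,P,P,P,P,P,P,P,P,P,P,P,P,P,P,P
VAGINA,P,P,P,P,P,P,P,P,P,P,P,P,P,P,P,P,P,P,P,P
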