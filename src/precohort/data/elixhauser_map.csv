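GROUP,ICD_PREFIX
hypertension_uncomplicated,I10
diabetes_uncomplicated,E11
solid_tumor,C18
solid_tumor,C19
solid_tumor,C20
solid_tumor,C25
solid_tumor,C26
solid_tumor,C34
solid_tumor,C50
solid_tumor,C61
metastatic_cancer,C77
metastatic_cancer,C78
metastatic_cancer,C79
metastatic_cancer,C80
depression,F32
depression,F33
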