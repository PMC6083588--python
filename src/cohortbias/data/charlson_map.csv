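condition,weight,prefix
mi,1,I21
mi,1,I22
mi,1,I252
chf,1,I50
pvd,1,I70
pvd,1,I71
cvd,1,I60
cvd,1,I61
cvd,1,I63
cvd,1,I64
dementia,1,F00
dementia,1,F01
dementia,1,F03
dementia,1,G30
copd,1,J41
copd,1,J43
copd,1,J44
rheumatic,1,M05
rheumatic,1,M06
pud,1,K25
pud,1,K26
pud,1,K27
pud,1,K28
mild_liver,1,B18
mild_liver,1,K73
mild_liver,1,K74
diabetes,1,E119
diabetes,1,E109
diabetes_complications,2,E112
diabetes_complications,2,E102
hemiplegia,2,G81
hemiplegia,2,G82
renal,2,N18
renal,2,N19
any_tumour,2,C18
any_tumour,2,C19
any_tumour,2,C20
any_tumour,2,C34
any_tumour,2,C50
any_tumour,2,C61
leukemia,2,C91
leukemia,2,C92
lymphoma,2,C81
lymphoma,2,C83
lymphoma,2,C85
moderate_severe_liver,3,K72
moderate_severe_liver,3,I85
metastatic_solid_tumour,6,C77
metastatic_solid_tumour,6,C78
metastatic_solid_tumour,6,C79
metastatic_solid_tumour,6,C80
aids,6,B20
aids,6,B21
aids,6,B22
aids,6,B24
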