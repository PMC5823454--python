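condition_id,name,is_elder_disease,is_index_copd,icd9_codes
copd,COPD,0,1,490-492;494;496
hypertension,Hypertension,0,0,
arrhythmia,Arrhythmia,0,0,
cerebrovascular_other,Other cerebrovascular syndrome,0,0,
iron_deficiency_anemia,Iron deficiency anemia,0,0,
gerd,Gastro-esophageal reflux disorder,0,0,
respiratory_other,"Respiratory disorder, other",0,0,
chronic_renal_failure,Chronic renal failure,1,0,
congestive_heart_failure,Congestive heart failure,0,0,
coronary_artery_disease,Coronary artery disease,1,0,
diverticulosis,Diverticulosis,0,0,
diabetes_mellitus,Diabetes mellitus,1,0,
degenerative_joint_disease,Degenerative joint disease,1,0,
depression,Depression,1,0,
incontinence,Incontinence,0,0,
dyslipidemia,Dyslipidemia,0,0,
cerebrovascular_accident,Cerebrovascular accident,0,0,
atherosclerosis,Atherosclerosis,1,0,
hypothyroidism,Hypothyroidism,0,0,
hematologic_other,"Hematology disorder, other",0,0,
benign_prostatic_hypertrophy,Benign prostatic hypertrophy,1,0,
varicose_veins,Varicose veins,0,0,
neurologic_other,"Neurologic disorder, other",0,0,
endocrine_other,"Endocrinopathy, other",0,0,
valvulopathy,Valvulopathy,0,0,
dementia,Dementia,1,0,
osteoporosis,Osteoporosis,1,0,
skin_ulcer,Skin ulcer,0,0,
eczema,Eczema,0,0,
cataract,Cataract,1,0,
paralytic_syndromes,Paralytic syndromes,0,0,
neuritis,Neuritis,0,0,
cirrhosis,Cirrhosis,0,0,
substance_abuse,Substance abuse,0,0,
anxiety,Anxiety,0,0,
aortic_aneurysm,Aortic aneurysm,0,0,
obesity,Obesity,0,0,
hearing_loss,Hearing loss,1,0,
skin_cancer,Skin cancer,1,0,
lung_cancer,Lung cancer,1,0,
condition_041,Synthetic chronic condition 41,0,0,
condition_042,Synthetic chronic condition 42,0,0,
condition_043,Synthetic chronic condition 43,0,0,
condition_044,Synthetic chronic condition 44,0,0,
condition_045,Synthetic chronic condition 45,0,0,
condition_046,Synthetic chronic condition 46,0,0,
condition_047,Synthetic chronic condition 47,0,0,
condition_048,Synthetic chronic condition 48,0,0,
condition_049,Synthetic chronic condition 49,0,0,
condition_050,Synthetic chronic condition 50,0,0,
condition_051,Synthetic chronic condition 51,0,0,
condition_052,Synthetic chronic condition 52,0,0,
condition_053,Synthetic chronic condition 53,0,0,
condition_054,Synthetic chronic condition 54,0,0,
condition_055,Synthetic chronic condition 55,0,0,
condition_056,Synthetic chronic condition 56,0,0,
condition_057,Synthetic chronic condition 57,0,0,
condition_058,Synthetic chronic condition 58,0,0,
condition_059,Synthetic chronic condition 59,0,0,
condition_060,Synthetic chronic condition 60,0,0,
condition_061,Synthetic chronic condition 61,0,0,
condition_062,Synthetic chronic condition 62,0,0,
condition_063,Synthetic chronic condition 63,0,0,
condition_064,Synthetic chronic condition 64,0,0,
condition_065,Synthetic chronic condition 65,0,0,
condition_066,Synthetic chronic condition 66,0,0,
condition_067,Synthetic chronic condition 67,0,0,
condition_068,Synthetic chronic condition 68,0,0,
condition_069,Synthetic chronic condition 69,0,0,
condition_070,Synthetic chronic condition 70,0,0,
condition_071,Synthetic chronic condition 71,0,0,
condition_072,Synthetic chronic condition 72,0,0,
condition_073,Synthetic chronic condition 73,0,0,
condition_074,Synthetic chronic condition 74,0,0,
condition_075,Synthetic chronic condition 75,0,0,
condition_076,Synthetic chronic condition 76,0,0,
condition_077,Synthetic chronic condition 77,0,0,
condition_078,Synthetic chronic condition 78,0,0,
condition_079,Synthetic chronic condition 79,0,0,
condition_080,Synthetic chronic condition 80,0,0,
condition_081,Synthetic chronic condition 81,0,0,
condition_082,Synthetic chronic condition 82,0,0,
condition_083,Synthetic chronic condition 83,0,0,
condition_084,Synthetic chronic condition 84,0,0,
condition_085,Synthetic chronic condition 85,0,0,
condition_086,Synthetic chronic condition 86,0,0,
condition_087,Synthetic chronic condition 87,0,0,
condition_088,Synthetic chronic condition 88,0,0,
condition_089,Synthetic chronic condition 89,0,0,
condition_090,Synthetic chronic condition 90,0,0,
condition_091,Synthetic chronic condition 91,0,0,
condition_092,Synthetic chronic condition 92,0,0,
condition_093,Synthetic chronic condition 93,0,0,
condition_094,Synthetic chronic condition 94,0,0,
condition_095,Synthetic chronic condition 95,0,0,
condition_096,Synthetic chronic condition 96,0,0,
condition_097,Synthetic chronic condition 97,0,0,
condition_098,Synthetic chronic condition 98,0,0,
condition_099,Synthetic chronic condition 99,0,0,
condition_100,Synthetic chronic condition 100,0,0,
condition_101,Synthetic chronic condition 101,0,0,
condition_102,Synthetic chronic condition 102,0,0,
condition_103,Synthetic chronic condition 103,0,0,
condition_104,Synthetic chronic condition 104,0,0,
condition_105,Synthetic chronic condition 105,0,0,
condition_106,Synthetic chronic condition 106,0,0,
condition_107,Synthetic chronic condition 107,0,0,
condition_108,Synthetic chronic condition 108,0,0,
condition_109,Synthetic chronic condition 109,0,0,
condition_110,Synthetic chronic condition 110,0,0,
condition_111,Synthetic chronic condition 111,0,0,
condition_112,Synthetic chronic condition 112,0,0,
condition_113,Synthetic chronic condition 113,0,0,
condition_114,Synthetic chronic condition 114,0,0,
condition_115,Synthetic chronic condition 115,0,0,
condition_116,Synthetic chronic condition 116,0,0,
condition_117,Synthetic chronic condition 117,0,0,
condition_118,Synthetic chronic condition 118,0,0,
condition_119,Synthetic chronic condition 119,0,0,
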