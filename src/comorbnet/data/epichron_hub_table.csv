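group,rank,condition_id,prevalence_pct,degree
copd,1,iron_deficiency_anemia,8,80
copd,2,cerebrovascular_other,9.9,76
copd,3,gerd,2.4,75
copd,4,respiratory_other,9.5,75
copd,5,arrhythmia,14.4,68
copd,6,hypertension,55.6,65
copd,7,atherosclerosis,2.2,64
copd,8,congestive_heart_failure,11.4,64
copd,9,depression,14.5,62
copd,10,chronic_renal_failure,3.4,62
copd,11,diverticulosis,4.2,61
copd,12,coronary_artery_disease,9.7,57
copd,13,valvulopathy,4.9,56
copd,14,osteoporosis,10.5,55
copd,15,hematologic_other,3.9,55
copd,16,benign_prostatic_hypertrophy,22.1,55
copd,17,diabetes_mellitus,22.1,54
copd,18,incontinence,9.1,54
copd,19,skin_ulcer,3.9,53
copd,20,degenerative_joint_disease,24.1,53
copd,21,neuritis,3.2,52
copd,22,varicose_veins,15.1,51
copd,23,endocrine_other,3.2,51
copd,24,cirrhosis,1.9,51
copd,25,neurologic_other,5.5,51
copd,26,substance_abuse,4.5,49
copd,27,hypothyroidism,7.9,48
copd,28,aortic_aneurysm,0.7,46
copd,29,obesity,15.9,46
copd,30,anxiety,3.6,46
control,1,arrhythmia,6.3,68
control,2,cerebrovascular_other,3.6,67
control,3,iron_deficiency_anemia,3.9,67
control,4,respiratory_other,1.2,66
control,5,hypertension,46,64
control,6,chronic_renal_failure,0.8,62
control,7,congestive_heart_failure,2.9,58
control,8,coronary_artery_disease,5.1,57
control,9,diverticulosis,2,57
control,10,diabetes_mellitus,16.8,56
control,11,degenerative_joint_disease,19.7,55
control,12,depression,9,55
control,13,incontinence,5.2,54
control,14,dyslipidemia,32.3,53
control,15,cerebrovascular_accident,6.6,53
control,16,atherosclerosis,0.4,52
control,17,hypothyroidism,5.5,52
control,18,gerd,0.5,52
control,19,hematologic_other,1.8,52
control,20,benign_prostatic_hypertrophy,16.2,51
control,21,varicose_veins,11.1,49
control,22,neurologic_other,3.5,49
control,23,endocrine_other,1.5,47
control,24,valvulopathy,1.9,46
control,25,dementia,3.4,46
control,26,osteoporosis,7.1,45
control,27,skin_ulcer,2,44
control,28,eczema,7.9,43
control,29,cataract,11.5,43
control,30,paralytic_syndromes,0.3,42
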