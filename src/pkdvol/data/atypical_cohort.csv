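patient_id,age,sex,serum_creatinine,egfr,egfr_slope,hypertension,referral_reason,smoking,diabetes,extrarenal_involvement,family_history_positive,pattern,httkv,tcv,tcv_percent,rtv
1,44,F,0.70,100,0.78,False,ultrasound_for_family_history,no,False,True,True,bilateral_atrophy,163,28,17.5,135
2,68,F,0.96,61,-0.86,True,incidental,no,True,False,True,lopsided,1644,1216,73.9,428
3,32,F,0.82,88,-1.10,False,ultrasound_for_symptoms,no,False,False,False,unilateral,1630,1313,80.5,317
4,47,F,0.76,86,1.22,True,ultrasound_for_family_history,former,False,True,True,bilateral_atrophy,234,47,20.3,187
5,48,M,1.40,57,8.59,True,incidental,no,False,False,True,lopsided,574,311,54.1,263
6,49,F,0.71,72,0.83,True,ultrasound_for_symptoms,no,False,True,True,lopsided,5571,4663,84.9,908
7,45,F,0.80,77,-2.23,False,ultrasound_for_family_history,no,False,False,True,mild_lopsided,581,230,39.6,351
8,63,F,0.76,84,-3.35,False,ultrasound_for_family_history,no,False,True,True,asymmetric,1472,914,62.1,558
9,71,M,1.13,78,-1.96,True,incidental,no,False,True,False,lopsided,2620,2201,84.0,419
10,69,F,1.27,43,-7.14,True,incidental,no,False,True,False,asymmetric,2100,1295,61.7,805
11,70,M,1.20,62,-0.92,True,ultrasound_for_symptoms,yes,False,True,True,lopsided,5532,4600,83.1,932
12,47,M,1.14,82,1.36,False,incidental,no,False,True,True,unilateral,598,293,49.0,305
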