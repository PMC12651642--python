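feature,weight
Hct,0.2989
MCHC,0.1482
MCH,0.1127
BMI,0.0991
Hemoglobin_Level,0.0683
RBC_Count,0.0677
RDW,0.0582
Family_History_Thalassemia,0.0534
Socioeconomic_Status,0.0508
MCV,0.0428
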