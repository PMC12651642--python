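row,column,value
Hct,MCHC,3
Hct,BMI,5
Hct,MCH,4
Hct,RDW,3
Hct,RBC_Count,5
Hct,Hemoglobin_Level,7
Hct,Family_History_Thalassemia,6
Hct,Socioeconomic_Status,4
Hct,MCV,5
MCHC,BMI,2
MCHC,MCH,1
MCHC,RDW,3
MCHC,RBC_Count,4
MCHC,Hemoglobin_Level,5
MCHC,Family_History_Thalassemia,3
MCHC,Socioeconomic_Status,2
MCHC,MCV,3
BMI,MCH,1
BMI,RDW,2
BMI,RBC_Count,3
BMI,Hemoglobin_Level,4
BMI,Family_History_Thalassemia,2
BMI,Socioeconomic_Status,1
BMI,MCV,2
MCH,RDW,2
MCH,RBC_Count,3
MCH,Hemoglobin_Level,4
MCH,Family_History_Thalassemia,2
MCH,Socioeconomic_Status,2
MCH,MCV,2
RDW,RBC_Count,1
RDW,Hemoglobin_Level,2
RDW,Family_History_Thalassemia,1
RDW,Socioeconomic_Status,1
RDW,MCV,1
RBC_Count,Hemoglobin_Level,3
RBC_Count,Family_History_Thalassemia,2
RBC_Count,Socioeconomic_Status,2
RBC_Count,MCV,2
Hemoglobin_Level,Family_History_Thalassemia,4
Hemoglobin_Level,Socioeconomic_Status,3
Hemoglobin_Level,MCV,3
Family_History_Thalassemia,Socioeconomic_Status,2
Family_History_Thalassemia,MCV,2
Socioeconomic_Status,MCV,1
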