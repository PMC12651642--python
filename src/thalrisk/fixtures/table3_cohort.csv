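Patient_ID,Age,BMI,Hemoglobin_Level,Family_History_Thalassemia,Genetic_Marker_Presence,Socioeconomic_Status,Education_Level,Residence,Parity,Carrier_Status,Hct,MCV,MCH,MCHC,RDW,RBC_Count
1,36,24.0,11.8,No,1,Middle,Higher Secondary,Rural,0,Non-Car.,36.0,72.3,22.1,31.3,14.2,5.25
2,39,22.6,10.4,No,0,Low,Secondary,Urban,3,Non-Car.,36.8,69.9,23.7,33.3,12.3,5.34
3,22,21.9,9.3,Yes,1,Middle,Secondary,Rural,0,Non-Car.,30.8,62.7,24.6,31.0,11.6,4.99
4,18,19.6,12.2,No,0,Middle,Secondary,Urban,1,Non-Car.,29.0,63.7,22.3,33.6,14.0,4.55
5,27,22.5,9.1,No,0,Low,Secondary,Rural,1,Non-Car.,29.2,76.9,19.9,33.3,12.1,4.91
6,27,29.3,12.3,Yes,1,Middle,Secondary,Urban,3,Non-Car.,31.3,62.0,19.2,30.3,14.3,5.22
7,37,19.3,10.5,No,0,Low,Primary,Urban,3,Non-Car.,33.3,70.7,19.0,31.1,12.7,5.18
8,39,27.4,10.5,No,0,High,Primary,Rural,2,Carrier,32.8,62.9,20.3,34.0,11.2,5.87
9,31,22.0,11.5,No,0,Low,Primary,Urban,3,Non-Car.,32.4,67.4,23.0,31.0,12.5,4.95
10,36,22.6,10.5,No,0,Low,Primary,Urban,2,Carrier,29.2,75.5,23.1,31.7,12.1,4.96
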