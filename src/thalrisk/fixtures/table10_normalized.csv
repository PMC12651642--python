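entry,Hct,MCHC,MCH,BMI,Hemoglobin_Level,RBC_Count,RDW,Family_History_Thalassemia,Socioeconomic_Status,MCV
1,0.8889,0.2167,0.5857,0.4783,0.8444,0.5000,0.9143,0.0,1.0,0.6150
2,0.9778,0.5500,0.8143,0.3565,0.5333,0.5600,0.3714,0.0,0.5,0.4950
3,0.3111,0.1667,0.9429,0.2957,0.2889,0.3267,0.1714,1.0,1.0,0.1350
4,0.1111,0.6000,0.6143,0.0957,0.9333,0.0333,0.8571,0.0,1.0,0.1850
5,0.1333,0.5500,0.2714,0.3478,0.2444,0.2733,0.3143,0.0,0.5,0.8450
6,0.2667,0.4333,0.3000,0.4130,0.2444,0.3333,0.0857,1.0,0.5,0.5350
7,0.1778,0.5833,0.2714,0.4696,0.2000,0.2867,0.6286,0.0,0.0,0.8650
8,0.9333,0.6500,0.7857,0.3869,0.5111,0.4067,0.6857,0.0,1.0,0.4250
9,0.5556,0.4000,0.5000,0.3826,0.5333,0.3667,0.7429,1.0,0.0,0.5050
10,0.2222,0.5167,0.6143,0.4565,0.6444,0.2267,0.7429,0.0,0.5,0.8850
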