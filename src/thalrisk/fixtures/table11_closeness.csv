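id,closeness,risk_rank,risk_category
1,0.7064,141,High Risk
2,0.7433,73,High Risk
3,0.3414,992,Medium Risk
4,0.2414,1162,Low Risk
5,0.2906,1094,Low Risk
6,0.2471,1157,Low Risk
7,0.3601,961,Medium Risk
8,0.6082,410,Medium Risk
9,0.4325,835,Medium Risk
10,0.2744,1115,Low Risk
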