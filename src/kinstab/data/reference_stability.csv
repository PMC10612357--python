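protein,variant,state,tm_C,model,tertiary_change,dG_cd,dG_cd_se,m_cd,m_cd_se,mid_cd,dG_fl,dG_fl_se,m_fl,m_fl_se,mid_fl
MAPK1,WT,NP,55.0,two,no,2.51,0.22,0.91,0.09,2.76,2.79,0.16,1.34,0.08,2.08
MAPK1,WT,P,55.0,two,no,2.30,0.16,0.97,0.07,2.37,2.88,0.20,1.19,0.09,2.42
MAPK1,E81K,NP,55.0,three,yes,,,,,,,,,,
MAPK1,E81K,P,54.1,three,yes,,,,,,,,,,
MAPK1,R135K,NP,55.1,three,no,,,,,,,,,,
MAPK1,R135K,P,55.1,two,no,2.09,0.17,0.99,0.07,2.12,2.38,0.18,1.18,0.09,2.02
MAPK1,D162G,NP,49.0;60.0,two,yes,2.28,0.16,1.05,0.08,2.17,2.67,0.12,1.00,0.05,2.68
MAPK1,D162G,P,60.0,three,yes,,,,,,,,,,
MAPK1,R191H,NP,58.0,three,yes,,,,,,,,,,
MAPK1,R191H,P,58.1,two,yes,2.31,0.19,1.02,0.09,2.27,2.55,0.19,1.35,0.11,1.88
MAPK1,Y316F,NP,55.1,two,yes,2.54,0.23,1.09,0.10,2.32,2.78,0.25,1.39,0.13,2.00
MAPK1,Y316F,P,55.1,two,yes,1.46,0.09,0.93,0.05,1.57,2.37,0.19,1.09,0.09,2.17
MAPK1,P319S,NP,51.0,three,yes,,,,,,,,,,
MAPK1,P319S,P,55.1,three,yes,,,,,,,,,,
MAPK1,E322V,NP,57.1,three,yes,,,,,,,,,,
MAPK1,E322V,P,56.0,three,yes,,,,,,,,,,
MAPK1,E33Q,NP,54.1,two,yes,2.44,0.14,0.96,0.06,2.54,3.33,0.31,1.97,0.20,1.69
MAPK1,E33Q,P,59.0,three,yes,,,,,,,,,,
MAPK1,L121I,NP,55.0,two,yes,2.29,0.14,1.00,0.07,2.29,3.27,0.31,1.41,0.14,2.32
MAPK1,L121I,P,62.0,two,yes,1.73,0.11,1.12,0.07,1.55,2.82,0.21,1.46,0.12,1.93
MAPK1,L200F,NP,54.0,two,yes,2.27,0.16,0.96,0.07,2.36,2.88,0.16,1.44,0.08,2.00
MAPK1,L200F,P,56.1,two,yes,2.15,0.19,0.97,0.09,2.20,3.06,0.30,1.72,0.18,1.77
MAPK1,D235V,NP,52.1,two,yes,2.46,0.16,1.07,0.08,2.30,2.48,0.19,1.15,0.09,2.15
MAPK1,D235V,P,61.1,two,yes,1.77,0.11,1.07,0.07,1.65,2.41,0.23,1.10,0.12,2.18
MAPK3,WT,NP,46.0,two,no,1.84,0.12,0.93,0.07,1.98,2.26,0.14,1.11,0.08,2.04
MAPK3,WT,P,47.1,two,no,1.72,0.09,0.83,0.04,2.07,2.40,0.12,1.22,0.06,1.97
MAPK3,E98K,NP,52.0,three,no,,,,,,,,,,
MAPK3,E98K,P,47.1,three,no,,,,,,,,,,
MAPK3,R152W,NP,49.0,three,yes,,,,,,,,,,
MAPK3,R152W,P,42.0;58.0,three,yes,,,,,,,,,,
MAPK3,P336Q,NP,44.0,three,yes,,,,,,,,,,
MAPK3,P336Q,P,47.0,three,yes,,,,,,,,,,
MAPK3,E339V,NP,46.1,three,no,,,,,,,,,,
MAPK3,E339V,P,48.1,three,no,,,,,,,,,,
MAPK3,I73M,NP,45.0,three,yes,,,,,,,,,,
MAPK3,I73M,P,46.0;58.0,three,yes,,,,,,,,,,
MAPK3,Q79H,NP,44.1;59.0,three,yes,,,,,,,,,,
MAPK3,Q79H,P,47.1,three,yes,,,,,,,,,,
MAPK3,A160T,NP,42.1,three,yes,,,,,,,,,,
MAPK3,A160T,P,44.1,three,yes,,,,,,,,,,
MAPK3,T198I,NP,58.0;75.0,two,yes,1.45,0.11,0.99,0.07,1.62,2.31,0.09,1.01,0.42,2.29
MAPK3,T198I,P,48.0,three,yes,,,,,,,,,,
MAPK3,E214D,NP,48.0;59.0;74.0,three,yes,,,,,,,,,,
MAPK3,E214D,P,51.0;61.1,three,yes,,,,,,,,,,
MAPK3,L281I,NP,46.1,three,yes,,,,,,,,,,
MAPK3,L281I,P,47.1,three,yes,,,,,,,,,,
MAPK3,V290A,NP,47.0,three,yes,,,,,,,,,,
MAPK3,V290A,P,56.0,three,yes,,,,,,,,,,
MAPK3,R359W,NP,43.1,three,yes,,,,,,,,,,
MAPK3,R359W,P,56.1,three,yes,,,,,,,,,,
MAPK3,E362K,NP,44.1,three,yes,,,,,,,,,,
MAPK3,E362K,P,46.0,three,yes,,,,,,,,,,
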