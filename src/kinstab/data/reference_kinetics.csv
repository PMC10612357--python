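protein,variant,Km_uM,Km_se,kcat_per_s,enzyme_nM,efficiency,Vmax_uM_per_s,Tmax_C,Ea_kcal_mol,Ea_se
MAPK1,WT,1.81,0.29,2.20,5.0,1.22,1.10e-2,30.0,9.95,0.41
MAPK1,E81K,2.64,0.72,1.24,10.0,4.70e-1,1.24e-2,35.0,6.90,0.95
MAPK1,R135K,6.19,1.92,28.3,0.5,4.57,1.42e-2,35.0,7.02,0.90
MAPK1,D162G,1.43,0.47,9.30e-4,1437,6.50e-4,1.34e-3,40.0,6.94,0.96
MAPK1,R191H,55,,2.00e-2,2381,3.64e-4,4.83e-2,40.0,8.09,0.99
MAPK1,Y316F,1.57,0.3,6.83,1.0,4.35,6.83e-3,37.0,5.74,0.26
MAPK1,P319S,4.26,1.11,3.62e-1,100,8.50e-2,3.62e-2,35.0,7.56,0.31
MAPK1,E322V,2.81,0.68,3.80,5.0,1.35,1.90e-2,37.0,3.99,0.26
MAPK1,E33Q,3.90,0.67,1.98,5.0,5.08e-1,9.91e-3,25.0,11.1,1.24
MAPK1,L121I,7.12,2.09,7.20e-2,390.0,1.01e-2,2.80e-2,35.0,8.97,1.40
MAPK1,L200F,3.23,0.4,2.43e-2,500,7.52e-3,1.21e-2,30.0,5.76,0.86
MAPK1,D235V,3.97,0.67,3.10e-1,50,7.81e-2,1.55e-2,37.0,8.60,0.88
MAPK3,WT,3.17,0.59,2.05,8.0,0.65,1.638e-2,37.0,4.28,0.28
MAPK3,E98K,2.46,0.43,2.65,10.0,1.08,2.65e-2,25.0,5.88,1.12
MAPK3,R152W,11.14,1.8,1.80,15.5,0.16,2.79e-2,40.0,5.57,0.28
MAPK3,P336Q,3.52,0.49,0.80,25.0,0.23,2.00e-2,37.0,6.26,0.81
MAPK3,E339V,2.91,0.59,1.07,10.0,0.37,1.07e-2,30.0,4.81,0.71
MAPK3,I73M,5.30,0.80,1.71,15.0,0.32,2.56e-2,40.0,4.83,0.38
MAPK3,Q79H,3.31,0.44,0.16,122,0.05,2.01e-2,25.0,8.61,1.82
MAPK3,A160T,3.41,0.72,2.06,8.00,0.60,1.65e-2,25.0,9.32,1.74
MAPK3,T198I,3.27,0.45,10.74,40.0,3.28,4.30e-1,25.0,8.16,1.87
MAPK3,E214D,8.51,1.20,0.49,90.0,0.06,4.40e-2,37.0,8.75,0.83
MAPK3,L281I,2.23,0.37,0.93,10.0,0.42,9.27e-3,30.0,10.2,0.59
MAPK3,V290A,14.49,1.60,1.27,50.0,0.09,6.34e-2,20.0,12.7,1.95
MAPK3,R359W,3.17,0.48,1.47,10.0,0.46,1.47e-2,35.0,6.37,0.68
MAPK3,E362K,6.55,0.52,1.14,20.0,0.17,2.28e-2,25.0,11.1,0.52
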