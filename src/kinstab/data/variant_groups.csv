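protein,substitution,group
MAPK1,E81K,I
MAPK1,R135K,I
MAPK1,D162G,I
MAPK1,R191H,I
MAPK1,Y316F,I
MAPK1,P319S,II
MAPK1,E322V,II
MAPK1,E33Q,III
MAPK1,L121I,III
MAPK1,L200F,III
MAPK1,D235V,III
MAPK3,E98K,I
MAPK3,R152W,I
MAPK3,P336Q,II
MAPK3,E339V,II
MAPK3,I73M,III
MAPK3,Q79H,III
MAPK3,A160T,III
MAPK3,T198I,III
MAPK3,E214D,III
MAPK3,L281I,III
MAPK3,V290A,III
MAPK3,R359W,III
MAPK3,E362K,III
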