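start,end,disease_category
A00,B99,infections
C00,D49,neoplasms
D50,D89,OTHER
E00,E89,endocrine
F01,F99,mental_health
G00,G99,nervous_system
H00,H95,OTHER
I00,I99,cardiovascular
J00,J99,respiratory
K00,K95,gastrointestinal
L00,L99,OTHER
M00,M99,musculoskeletal
N00,N99,genitourinary
O00,O9A,OTHER
P00,P96,OTHER
Q00,Q99,OTHER
R00,R99,OTHER
S00,T88,injuries_external
U00,U85,OTHER
V00,Y99,injuries_external
Z00,Z99,OTHER
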