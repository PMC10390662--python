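name,min,max,cost,group
NEAA,0.5,5,0,1
EAA,0.5,5,0,1
V,0.5,5,0,1
Salt,0.5,5,0,1
Metal,0.5,5,0,1
DNA,0.5,5,0,1
Fat,0.5,5,0,1
SS,7.00e-06,7.00e-05,0,0
AA,0.03,0.30,0,0
Gluc,1.35,13.50,0,0
Gluta,0.22,2.20,0,0
Pyruv,0.03,0.30,0,0
NaCl,1.40,14.0,0,0
I,0.01,0.10,0.03,0
T,5.00e-03,0.05,0.004,0
FGF2,3.00e-05,3.00e-04,0.63,0
TGFb1,1.00e-06,1.00e-05,0.09,0
EGF,0,2.50e-05,0.003,0
P,0,2.50e-05,0,0
Estra,0,1.25e-05,0,0
IL-6,0,6.25e-05,0.08,0
LIF,0,1.25e-05,0.02,0
TGFb3,0,1.60e-05,0.04,0
HGF,0,2.50e-05,0.03,0
PDGF,0,2.50e-05,0.03,0
PEDF,0,2.50e-05,0.04,0
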