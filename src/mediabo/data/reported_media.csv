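label,NEAA,EAA,V,Salt,Metal,DNA,Fat,SS,AA,Gluc,Gluta,Pyruv,NaCl,I,T,FGF2,TGFb1,EGF,P,Estra,IL-6,LIF,TGFb3,HGF,PDGF,PEDF
Control,1.00,1.00,1.00,1.00,1.00,1.00,1.00,1.40e-05,0.06,4.05,0.43,0.06,7.00,0.10,1.00e-02,9.00e-05,2.00e-06,0,0,0,0,0,0,0,0,0
CBCB-0,0.75,0.90,3.60,0.50,5.00,1.95,2.75,4.41e-05,0.18,1.62,1.35,0.20,4.76,0.01,5.00e-03,3.00e-05,1.00e-06,4.25e-06,1.73e-05,5.75e-06,1.13e-05,3.75e-07,0,0,0,0
CBCB-1,1.50,1.35,4.30,2.50,4.80,3.05,1.25,4.83e-05,0.21,9.59,1.95,0.25,4.76,0.01,3.35e-02,1.29e-04,1.00e-06,2.25e-05,5.25e-06,5.00e-07,5.00e-06,8.75e-07,0,0,0,0
CBCB-2,1.55,1.40,2.25,1.75,3.40,2.95,2.20,3.99e-05,0.23,3.51,1.58,0.13,5.60,0.02,1.95e-02,1.32e-04,1.70e-06,9.25e-06,1.93e-05,4.75e-06,3.94e-05,4.00e-06,4.48e-06,1.00e-06,9.25e-06,2.50e-06
CBCB-3,1.20,0.95,1.60,0.90,3.55,2.00,2.65,4.41e-05,0.23,6.89,1.54,0.11,3.64,0.02,2.20e-02,1.35e-04,2.80e-06,1.10e-05,1.50e-05,2.38e-06,3.94e-05,1.63e-06,7.36e-06,2.00e-06,9.50e-06,3.75e-06
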