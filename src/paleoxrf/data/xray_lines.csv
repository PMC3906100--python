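# Characteristic X-ray emission lines, Siegbahn notation, energies in keV.
# Energies: standard fluorescence-line tabulation (X-ray data booklet /
# Deslattes et al. compilation), snapshot v1 (2014-era values, static asset).
# rel_intensity is the approximate branching fraction within the named group
# (Ka, Kb, La, Lb, Lg); fractions sum to 1 within each (element, group).
element,series,group,siegbahn,energy_keV,rel_intensity
Si,K,Ka,Ka1,1.73998,0.67
Si,K,Ka,Ka2,1.73938,0.33
Si,K,Kb,Kb1,1.83594,1.0
P,K,Ka,Ka1,2.0137,0.67
P,K,Ka,Ka2,2.0127,0.33
P,K,Kb,Kb1,2.1390,1.0
S,K,Ka,Ka1,2.3078,0.67
S,K,Ka,Ka2,2.3066,0.33
S,K,Kb,Kb1,2.4640,1.0
Cl,K,Ka,Ka1,2.6224,0.67
Cl,K,Ka,Ka2,2.6208,0.33
Cl,K,Kb,Kb1,2.8156,1.0
K,K,Ka,Ka1,3.3138,0.67
K,K,Ka,Ka2,3.3111,0.33
K,K,Kb,Kb1,3.5896,1.0
Ca,K,Ka,Ka1,3.6917,0.67
Ca,K,Ka,Ka2,3.6881,0.33
Ca,K,Kb,Kb1,4.0127,1.0
Ti,K,Ka,Ka1,4.5108,0.67
Ti,K,Ka,Ka2,4.5049,0.33
Ti,K,Kb,Kb1,4.9318,1.0
V,K,Ka,Ka1,4.9522,0.67
V,K,Ka,Ka2,4.9446,0.33
V,K,Kb,Kb1,5.4273,1.0
Cr,K,Ka,Ka1,5.4147,0.67
Cr,K,Ka,Ka2,5.4055,0.33
Cr,K,Kb,Kb1,5.9467,1.0
Mn,K,Ka,Ka1,5.8988,0.67
Mn,K,Ka,Ka2,5.8877,0.33
Mn,K,Kb,Kb1,6.4904,1.0
Fe,K,Ka,Ka1,6.4038,0.67
Fe,K,Ka,Ka2,6.3908,0.33
Fe,K,Kb,Kb1,7.0580,1.0
Ni,K,Ka,Ka1,7.4782,0.67
Ni,K,Ka,Ka2,7.4609,0.33
Ni,K,Kb,Kb1,8.2647,1.0
Cu,K,Ka,Ka1,8.0478,0.67
Cu,K,Ka,Ka2,8.0278,0.33
Cu,K,Kb,Kb1,8.9053,1.0
Zn,K,Ka,Ka1,8.6389,0.67
Zn,K,Ka,Ka2,8.6158,0.33
Zn,K,Kb,Kb1,9.5720,1.0
Ga,K,Ka,Ka1,9.2517,0.67
Ga,K,Ka,Ka2,9.2248,0.33
Ga,K,Kb,Kb1,10.2642,1.0
Br,K,Ka,Ka1,11.9242,0.67
Br,K,Ka,Ka2,11.8776,0.33
Br,K,Kb,Kb1,13.2914,1.0
Rb,K,Ka,Ka1,13.3953,0.67
Rb,K,Ka,Ka2,13.3358,0.33
Rb,K,Kb,Kb1,14.9613,1.0
Sr,K,Ka,Ka1,14.1650,0.67
Sr,K,Ka,Ka2,14.0979,0.33
Sr,K,Kb,Kb1,15.8357,1.0
Y,K,Ka,Ka1,14.9584,0.67
Y,K,Ka,Ka2,14.8829,0.33
Y,K,Kb,Kb1,16.7378,1.0
La,L,La,La1,4.6510,0.905
La,L,La,La2,4.6342,0.095
La,L,Lb,Lb1,5.0421,0.72
La,L,Lb,Lb2,5.3838,0.28
La,L,Lg,Lg1,5.7885,1.0
Ce,L,La,La1,4.8402,0.905
Ce,L,La,La2,4.8230,0.095
Ce,L,Lb,Lb1,5.2622,0.72
Ce,L,Lb,Lb2,5.6134,0.28
Ce,L,Lg,Lg1,6.0520,1.0
Nd,L,La,La1,5.2304,0.905
Nd,L,La,La2,5.2077,0.095
Nd,L,Lb,Lb1,5.7216,0.72
Nd,L,Lb,Lb2,6.0894,0.28
Nd,L,Lg,Lg1,6.6021,1.0
Sm,L,La,La1,5.6361,0.905
Sm,L,La,La2,5.6090,0.095
Sm,L,Lb,Lb1,6.2051,0.72
Sm,L,Lb,Lb2,6.5870,0.28
Sm,L,Lg,Lg1,7.1780,1.0
Gd,L,La,La1,6.0572,0.905
Gd,L,La,La2,6.0250,0.095
Gd,L,Lb,Lb1,6.7132,0.72
Gd,L,Lb,Lb2,7.1028,0.28
Gd,L,Lg,Lg1,7.7858,1.0
Dy,L,La,La1,6.4952,0.905
Dy,L,La,La2,6.4577,0.095
Dy,L,Lb,Lb1,7.2477,0.72
Dy,L,Lb,Lb2,7.6359,0.28
Dy,L,Lg,Lg1,8.4188,1.0
Er,L,La,La1,6.9487,0.905
Er,L,La,La2,6.9050,0.095
Er,L,Lb,Lb1,7.8109,0.72
Er,L,Lb,Lb2,8.1890,0.28
Er,L,Lg,Lg1,9.0889,1.0
Yb,L,La,La1,7.4157,0.905
Yb,L,La,La2,7.3673,0.095
Yb,L,Lb,Lb1,8.4018,0.72
Yb,L,Lb,Lb2,8.7588,0.28
Yb,L,Lg,Lg1,9.7801,1.0
Pb,L,La,La1,10.5515,0.905
Pb,L,La,La2,10.4495,0.095
Pb,L,Lb,Lb1,12.6137,0.72
Pb,L,Lb,Lb2,12.6226,0.28
Pb,L,Lg,Lg1,14.7644,1.0
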