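# Absorption-edge energies (keV) and approximate fluorescence yields.
# K edges / omega_K after Krause (1979); L3 edges / omega_L3 likewise.
# Used by the forward simulator's simplified sensitivity model and by the
# excitation check in the line model (a series is excitable only if its
# edge lies below the beam energy).
element,shell,edge_keV,fluor_yield
Si,K,1.8390,0.050
P,K,2.1455,0.063
S,K,2.4720,0.078
Cl,K,2.8224,0.097
K,K,3.6074,0.140
Ca,K,4.0381,0.163
Ti,K,4.9664,0.219
V,K,5.4651,0.250
Cr,K,5.9892,0.282
Mn,K,6.5390,0.314
Fe,K,7.1120,0.347
Ni,K,8.3328,0.414
Cu,K,8.9789,0.445
Zn,K,9.6586,0.479
Ga,K,10.3671,0.507
Br,K,13.4737,0.618
Rb,K,15.1997,0.667
Sr,K,16.1046,0.690
Y,K,17.0384,0.710
La,L,5.4827,0.106
Ce,L,5.7234,0.112
Nd,L,6.2079,0.124
Sm,L,6.7162,0.137
Gd,L,7.2428,0.155
Dy,L,7.7901,0.168
Er,L,8.3579,0.190
Yb,L,8.9436,0.210
Pb,L,13.0352,0.384
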