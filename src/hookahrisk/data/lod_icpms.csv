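# ICP-MS method detection limits in the measured solution, ug/L.
element,lod_ug_l
Al,0.01
As,0.007
B,0.2
Ba,0.01
Ca,0.1
Cd,0.01
Ce,0.01
Co,0.1
Cr,0.1
Cu,0.01
Fe,4.1
Hg,0.03
K,0.5
Mg,0.01
Mn,0.4
Mo,0.01
Na,0.01
Ni,0.02
P,43
Pb,0.02
S,8.1
Sb,0.02
Se,0.4
Si,6.1
Sn,0.02
Sr,0.01
Ti,0.02
V,0.02
Zn,40.1
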