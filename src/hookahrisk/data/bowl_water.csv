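# Element concentrations transcribed from the published study tables.
# Solids (raw tobacco, combustion ash): ppm = mg/kg, ppb = ug/kg.
# Bowl water collected after smoking: ppm = mg/L, ppb = ug/L.
# '<x' marks a left-censored cell (below the detection limit x);
# '*****' marks a cell not reported at all.
# note=low_confidence flags cells whose printed column boundaries are
# ambiguous (digits of adjacent columns run together in the source);
# the recorded split keeps each value inside its column's range across
# samples. No headline result depends on these cells.
sample_id,compartment,element,value,unit,note
Apple,water,Al,21,mg/L,low_confidence
Apple,water,As,36,ug/L,low_confidence
Apple,water,B,739,mg/L,low_confidence
Apple,water,Ba,83,mg/L,low_confidence
Apple,water,Ca,105,mg/L,
Apple,water,Cd,<5,ug/L,
Apple,water,Ce,<10,mg/L,
Apple,water,Co,<10,mg/L,
Apple,water,Cr,<10,mg/L,
Apple,water,Cu,11,mg/L,
Apple,water,Fe,46,mg/L,
Apple,water,Hg,<10,ug/L,
Apple,water,K,8.96,mg/L,
Apple,water,Mg,17.59,mg/L,
Apple,water,Mn,42,mg/L,
Apple,water,Mo,<20,mg/L,
Apple,water,Na,30.09,mg/L,
Apple,water,Ni,<20,mg/L,
Apple,water,P,416,mg/L,
Apple,water,Pb,16,mg/L,
Apple,water,S,*****,mg/L,
Apple,water,Sb,<20,mg/L,
Apple,water,Se,<20,mg/L,
Apple,water,Si,13.90,mg/L,
Apple,water,Sn,<20,mg/L,
Apple,water,Sr,694,mg/L,
Apple,water,Ti,<50,mg/L,
Apple,water,V,<50,mg/L,
Apple,water,Zn,58,mg/L,
Blueberry,water,Al,81,mg/L,
Blueberry,water,As,<5,ug/L,
Blueberry,water,B,687,mg/L,
Blueberry,water,Ba,85,mg/L,
Blueberry,water,Ca,108,mg/L,
Blueberry,water,Cd,<5,ug/L,
Blueberry,water,Ce,<10,mg/L,
Blueberry,water,Co,<10,mg/L,
Blueberry,water,Cr,<10,mg/L,
Blueberry,water,Cu,26,mg/L,
Blueberry,water,Fe,42,mg/L,
Blueberry,water,Hg,<10,ug/L,
Blueberry,water,K,4.42,mg/L,
Blueberry,water,Mg,18.49,mg/L,
Blueberry,water,Mn,19,mg/L,
Blueberry,water,Mo,<20,mg/L,
Blueberry,water,Na,32.56,mg/L,
Blueberry,water,Ni,39.00,mg/L,
Blueberry,water,P,332,mg/L,low_confidence
Blueberry,water,Pb,384,mg/L,low_confidence
Blueberry,water,S,*****,mg/L,
Blueberry,water,Sb,<20,mg/L,
Blueberry,water,Se,<20,mg/L,
Blueberry,water,Si,14.77,mg/L,
Blueberry,water,Sn,53,mg/L,
Blueberry,water,Sr,751,mg/L,
Blueberry,water,Ti,<50,mg/L,
Blueberry,water,V,<50,mg/L,
Blueberry,water,Zn,217,mg/L,
Orange,water,Al,66,mg/L,
Orange,water,As,28,ug/L,low_confidence
Orange,water,B,668,mg/L,low_confidence
Orange,water,Ba,87,mg/L,low_confidence
Orange,water,Ca,105,mg/L,
Orange,water,Cd,<5,ug/L,
Orange,water,Ce,<10,mg/L,
Orange,water,Co,<10,mg/L,
Orange,water,Cr,<10,mg/L,
Orange,water,Cu,24,mg/L,
Orange,water,Fe,67,mg/L,
Orange,water,Hg,<10,ug/L,
Orange,water,K,8.86,mg/L,
Orange,water,Mg,17.72,mg/L,
Orange,water,Mn,10,mg/L,
Orange,water,Mo,<20,mg/L,
Orange,water,Na,29.02,mg/L,
Orange,water,Ni,<20,mg/L,
Orange,water,P,361,mg/L,
Orange,water,Pb,96,mg/L,
Orange,water,S,*****,mg/L,
Orange,water,Sb,<20,mg/L,
Orange,water,Se,<20,mg/L,
Orange,water,Si,12.69,mg/L,
Orange,water,Sn,22,mg/L,
Orange,water,Sr,722,mg/L,
Orange,water,Ti,<50,mg/L,
Orange,water,V,<50,mg/L,
Orange,water,Zn,72,mg/L,
Khansar,water,Al,52,mg/L,
Khansar,water,As,<5,ug/L,
Khansar,water,B,657,mg/L,
Khansar,water,Ba,22,mg/L,
Khansar,water,Ca,55,mg/L,
Khansar,water,Cd,<5,ug/L,
Khansar,water,Ce,<10,mg/L,
Khansar,water,Co,<10,mg/L,
Khansar,water,Cr,<10,mg/L,
Khansar,water,Cu,29,mg/L,
Khansar,water,Fe,<50,mg/L,
Khansar,water,Hg,<10,ug/L,
Khansar,water,K,7.39,mg/L,
Khansar,water,Mg,6.55,mg/L,
Khansar,water,Mn,12,mg/L,
Khansar,water,Mo,<20,mg/L,
Khansar,water,Na,16.91,mg/L,
Khansar,water,Ni,<20,mg/L,
Khansar,water,P,51,mg/L,
Khansar,water,Pb,<20,mg/L,
Khansar,water,S,*****,mg/L,
Khansar,water,Sb,<20,mg/L,
Khansar,water,Se,<20,mg/L,
Khansar,water,Si,9.81,mg/L,
Khansar,water,Sn,<20,mg/L,
Khansar,water,Sr,303,mg/L,
Khansar,water,Ti,<50,mg/L,
Khansar,water,V,<50,mg/L,
Khansar,water,Zn,26,mg/L,
Borazjan,water,Al,36,mg/L,
Borazjan,water,As,<5,ug/L,
Borazjan,water,B,651,mg/L,
Borazjan,water,Ba,24,mg/L,
Borazjan,water,Ca,56,mg/L,
Borazjan,water,Cd,<5,ug/L,
Borazjan,water,Ce,<10,mg/L,
Borazjan,water,Co,<10,mg/L,
Borazjan,water,Cr,<10,mg/L,
Borazjan,water,Cu,<20,mg/L,
Borazjan,water,Fe,<50,mg/L,
Borazjan,water,Hg,<10,ug/L,
Borazjan,water,K,7.40,mg/L,
Borazjan,water,Mg,8.76,mg/L,
Borazjan,water,Mn,15,mg/L,
Borazjan,water,Mo,<20,mg/L,
Borazjan,water,Na,20.12,mg/L,
Borazjan,water,Ni,<20,mg/L,
Borazjan,water,P,67,mg/L,
Borazjan,water,Pb,22,mg/L,
Borazjan,water,S,*****,mg/L,
Borazjan,water,Sb,<20,mg/L,
Borazjan,water,Se,<20,mg/L,
Borazjan,water,Si,9.76,mg/L,
Borazjan,water,Sn,<20,mg/L,
Borazjan,water,Sr,339,mg/L,
Borazjan,water,Ti,<50,mg/L,
Borazjan,water,V,<50,mg/L,
Borazjan,water,Zn,29,mg/L,
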