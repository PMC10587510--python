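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
Apple,raw,Al,182.3,mg/kg,
Apple,raw,As,66,ug/kg,
Apple,raw,B,134.2,mg/kg,
Apple,raw,Ba,16.4,mg/kg,
Apple,raw,Ca,17214,mg/kg,
Apple,raw,Cd,221,ug/kg,
Apple,raw,Ce,1.4,mg/kg,
Apple,raw,Co,<0.5,mg/kg,
Apple,raw,Cr,<0.5,mg/kg,
Apple,raw,Cu,5.2,mg/kg,
Apple,raw,Fe,256.4,mg/kg,
Apple,raw,Hg,23,ug/kg,
Apple,raw,K,15422,mg/kg,
Apple,raw,Mg,3503,mg/kg,
Apple,raw,Mn,40.4,mg/kg,
Apple,raw,Mo,0.3,mg/kg,
Apple,raw,Na,6932.1,mg/kg,
Apple,raw,Ni,2.2,mg/kg,
Apple,raw,P,874.2,mg/kg,
Apple,raw,Pb,3.3,mg/kg,
Apple,raw,S,198,mg/kg,
Apple,raw,Sb,<1,mg/kg,
Apple,raw,Se,1.3,mg/kg,
Apple,raw,Si,203.5,mg/kg,
Apple,raw,Sn,3.7,mg/kg,
Apple,raw,Sr,161.8,mg/kg,
Apple,raw,Ti,2.4,mg/kg,
Apple,raw,V,0.7,mg/kg,
Apple,raw,Zn,16.2,mg/kg,
Blueberry,raw,Al,197.4,mg/kg,
Blueberry,raw,As,<50,ug/kg,
Blueberry,raw,B,121.3,mg/kg,
Blueberry,raw,Ba,14.2,mg/kg,
Blueberry,raw,Ca,9676,mg/kg,
Blueberry,raw,Cd,231,ug/kg,
Blueberry,raw,Ce,0.5,mg/kg,
Blueberry,raw,Co,0.8,mg/kg,
Blueberry,raw,Cr,<0.5,mg/kg,
Blueberry,raw,Cu,3.7,mg/kg,
Blueberry,raw,Fe,78.1,mg/kg,
Blueberry,raw,Hg,21,ug/kg,
Blueberry,raw,K,10576,mg/kg,
Blueberry,raw,Mg,1362,mg/kg,
Blueberry,raw,Mn,48.6,mg/kg,
Blueberry,raw,Mo,<0.5,mg/kg,
Blueberry,raw,Na,983.1,mg/kg,
Blueberry,raw,Ni,<0.5,mg/kg,
Blueberry,raw,P,595.6,mg/kg,
Blueberry,raw,Pb,1.5,mg/kg,
Blueberry,raw,S,100,mg/kg,
Blueberry,raw,Sb,<1,mg/kg,
Blueberry,raw,Se,1.9,mg/kg,
Blueberry,raw,Si,192.0,mg/kg,
Blueberry,raw,Sn,1.9,mg/kg,
Blueberry,raw,Sr,41.9,mg/kg,
Blueberry,raw,Ti,<1,mg/kg,
Blueberry,raw,V,<0.5,mg/kg,
Blueberry,raw,Zn,14.6,mg/kg,
Orange,raw,Al,171.4,mg/kg,
Orange,raw,As,3093,ug/kg,low_confidence
Orange,raw,B,116.9,mg/kg,low_confidence
Orange,raw,Ba,8.4,mg/kg,low_confidence
Orange,raw,Ca,6418,mg/kg,
Orange,raw,Cd,346,ug/kg,
Orange,raw,Ce,<0.5,mg/kg,
Orange,raw,Co,0.8,mg/kg,
Orange,raw,Cr,<0.5,mg/kg,
Orange,raw,Cu,2.3,mg/kg,
Orange,raw,Fe,47.8,mg/kg,
Orange,raw,Hg,22,ug/kg,
Orange,raw,K,9671,mg/kg,
Orange,raw,Mg,1752,mg/kg,
Orange,raw,Mn,42.7,mg/kg,
Orange,raw,Mo,<0.5,mg/kg,
Orange,raw,Na,544.3,mg/kg,
Orange,raw,Ni,<0.5,mg/kg,
Orange,raw,P,448.1,mg/kg,
Orange,raw,Pb,3.8,mg/kg,
Orange,raw,S,70,mg/kg,
Orange,raw,Sb,<1,mg/kg,
Orange,raw,Se,4.7,mg/kg,
Orange,raw,Si,182.1,mg/kg,
Orange,raw,Sn,<1,mg/kg,
Orange,raw,Sr,26.6,mg/kg,
Orange,raw,Ti,<1,mg/kg,
Orange,raw,V,<0.5,mg/kg,
Orange,raw,Zn,12.2,mg/kg,
Khansar,raw,Al,1836.2,mg/kg,
Khansar,raw,As,462,ug/kg,
Khansar,raw,B,223.4,mg/kg,
Khansar,raw,Ba,118.9,mg/kg,
Khansar,raw,Ca,66743,mg/kg,
Khansar,raw,Cd,269,ug/kg,
Khansar,raw,Ce,3.9,mg/kg,
Khansar,raw,Co,2.7,mg/kg,
Khansar,raw,Cr,4.7,mg/kg,
Khansar,raw,Cu,12.8,mg/kg,
Khansar,raw,Fe,2360.9,mg/kg,
Khansar,raw,Hg,72,ug/kg,
Khansar,raw,K,46276,mg/kg,
Khansar,raw,Mg,14179,mg/kg,
Khansar,raw,Mn,130.7,mg/kg,
Khansar,raw,Mo,2.9,mg/kg,
Khansar,raw,Na,71050.0,mg/kg,
Khansar,raw,Ni,8.0,mg/kg,
Khansar,raw,P,2513.0,mg/kg,
Khansar,raw,Pb,9.7,mg/kg,
Khansar,raw,S,683,mg/kg,
Khansar,raw,Sb,<1,mg/kg,
Khansar,raw,Se,4.1,mg/kg,
Khansar,raw,Si,243.7,mg/kg,
Khansar,raw,Sn,2.3,mg/kg,
Khansar,raw,Sr,699.1,mg/kg,
Khansar,raw,Ti,25.8,mg/kg,
Khansar,raw,V,4.2,mg/kg,
Khansar,raw,Zn,30.7,mg/kg,
Borazjan,raw,Al,984.6,mg/kg,
Borazjan,raw,As,237,ug/kg,
Borazjan,raw,B,223.6,mg/kg,
Borazjan,raw,Ba,60.4,mg/kg,
Borazjan,raw,Ca,66797,mg/kg,
Borazjan,raw,Cd,328,ug/kg,
Borazjan,raw,Ce,2.6,mg/kg,
Borazjan,raw,Co,1.2,mg/kg,
Borazjan,raw,Cr,2.8,mg/kg,
Borazjan,raw,Cu,12.9,mg/kg,
Borazjan,raw,Fe,1415.1,mg/kg,
Borazjan,raw,Hg,47,ug/kg,
Borazjan,raw,K,36826,mg/kg,
Borazjan,raw,Mg,18108,mg/kg,
Borazjan,raw,Mn,113.7,mg/kg,
Borazjan,raw,Mo,3.9,mg/kg,
Borazjan,raw,Na,45489.0,mg/kg,
Borazjan,raw,Ni,4.9,mg/kg,
Borazjan,raw,P,1928.5,mg/kg,
Borazjan,raw,Pb,5.9,mg/kg,
Borazjan,raw,S,937,mg/kg,
Borazjan,raw,Sb,<1,mg/kg,
Borazjan,raw,Se,3.3,mg/kg,
Borazjan,raw,Si,166.8,mg/kg,
Borazjan,raw,Sn,1.6,mg/kg,
Borazjan,raw,Sr,924.2,mg/kg,
Borazjan,raw,Ti,19.2,mg/kg,
Borazjan,raw,V,3.1,mg/kg,
Borazjan,raw,Zn,29.7,mg/kg,
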