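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
Apple,ash,Al,138.1,mg/kg,
Apple,ash,As,2031,ug/kg,
Apple,ash,B,126.2,mg/kg,
Apple,ash,Ba,18.3,mg/kg,
Apple,ash,Ca,20890,mg/kg,
Apple,ash,Cd,406,ug/kg,
Apple,ash,Ce,1.1,mg/kg,
Apple,ash,Co,1.0,mg/kg,
Apple,ash,Cr,<0.5,mg/kg,
Apple,ash,Cu,15.3,mg/kg,
Apple,ash,Fe,173.4,mg/kg,
Apple,ash,Hg,<50,ug/kg,
Apple,ash,K,20424,mg/kg,
Apple,ash,Mg,2850,mg/kg,
Apple,ash,Mn,40.4,mg/kg,
Apple,ash,Mo,<0.5,mg/kg,
Apple,ash,Na,2133.1,mg/kg,
Apple,ash,Ni,8.7,mg/kg,
Apple,ash,P,1249.2,mg/kg,
Apple,ash,Pb,6.5,mg/kg,
Apple,ash,S,240,mg/kg,
Apple,ash,Sb,<1,mg/kg,
Apple,ash,Se,<1,mg/kg,
Apple,ash,Si,256.2,mg/kg,
Apple,ash,Sn,<1,mg/kg,
Apple,ash,Sr,113.3,mg/kg,
Apple,ash,Ti,1.4,mg/kg,
Apple,ash,V,<0.5,mg/kg,
Apple,ash,Zn,25.8,mg/kg,
Blueberry,ash,Al,195.0,mg/kg,
Blueberry,ash,As,339,ug/kg,
Blueberry,ash,B,117.5,mg/kg,
Blueberry,ash,Ba,16.8,mg/kg,
Blueberry,ash,Ca,12481,mg/kg,
Blueberry,ash,Cd,806,ug/kg,
Blueberry,ash,Ce,<0.5,mg/kg,
Blueberry,ash,Co,0.5,mg/kg,
Blueberry,ash,Cr,<0.5,mg/kg,
Blueberry,ash,Cu,6.2,mg/kg,
Blueberry,ash,Fe,131.0,mg/kg,
Blueberry,ash,Hg,<50,ug/kg,
Blueberry,ash,K,11913,mg/kg,
Blueberry,ash,Mg,1318,mg/kg,
Blueberry,ash,Mn,55.5,mg/kg,
Blueberry,ash,Mo,<0.5,mg/kg,
Blueberry,ash,Na,700.9,mg/kg,
Blueberry,ash,Ni,4.4,mg/kg,
Blueberry,ash,P,862.1,mg/kg,
Blueberry,ash,Pb,2.1,mg/kg,
Blueberry,ash,S,146,mg/kg,
Blueberry,ash,Sb,<1,mg/kg,
Blueberry,ash,Se,<1,mg/kg,
Blueberry,ash,Si,172.1,mg/kg,
Blueberry,ash,Sn,2.2,mg/kg,
Blueberry,ash,Sr,53.6,mg/kg,
Blueberry,ash,Ti,<1,mg/kg,
Blueberry,ash,V,<0.5,mg/kg,
Blueberry,ash,Zn,19.4,mg/kg,
Orange,ash,Al,307.1,mg/kg,
Orange,ash,As,<50,ug/kg,
Orange,ash,B,132.8,mg/kg,
Orange,ash,Ba,21.6,mg/kg,
Orange,ash,Ca,27930,mg/kg,
Orange,ash,Cd,80,ug/kg,
Orange,ash,Ce,<0.5,mg/kg,
Orange,ash,Co,0.3,mg/kg,
Orange,ash,Cr,<0.5,mg/kg,
Orange,ash,Cu,9.7,mg/kg,
Orange,ash,Fe,280.3,mg/kg,
Orange,ash,Hg,126,ug/kg,
Orange,ash,K,13550,mg/kg,
Orange,ash,Mg,3457,mg/kg,
Orange,ash,Mn,24.2,mg/kg,
Orange,ash,Mo,0.6,mg/kg,
Orange,ash,Na,4493.5,mg/kg,
Orange,ash,Ni,2.8,mg/kg,
Orange,ash,P,982.1,mg/kg,
Orange,ash,Pb,6.7,mg/kg,
Orange,ash,S,188,mg/kg,
Orange,ash,Sb,<1,mg/kg,
Orange,ash,Se,1.4,mg/kg,
Orange,ash,Si,208.8,mg/kg,
Orange,ash,Sn,1.4,mg/kg,
Orange,ash,Sr,178.8,mg/kg,
Orange,ash,Ti,2.8,mg/kg,
Orange,ash,V,0.5,mg/kg,
Orange,ash,Zn,17.2,mg/kg,
Khansar,ash,Al,1043.1,mg/kg,
Khansar,ash,As,316,ug/kg,
Khansar,ash,B,209.6,mg/kg,
Khansar,ash,Ba,77.1,mg/kg,
Khansar,ash,Ca,58661,mg/kg,
Khansar,ash,Cd,375,ug/kg,
Khansar,ash,Ce,1.5,mg/kg,
Khansar,ash,Co,1.7,mg/kg,
Khansar,ash,Cr,2.7,mg/kg,
Khansar,ash,Cu,9.4,mg/kg,
Khansar,ash,Fe,1357.3,mg/kg,
Khansar,ash,Hg,38,ug/kg,
Khansar,ash,K,33543,mg/kg,
Khansar,ash,Mg,13058,mg/kg,
Khansar,ash,Mn,114.4,mg/kg,
Khansar,ash,Mo,3.0,mg/kg,
Khansar,ash,Na,48296.0,mg/kg,
Khansar,ash,Ni,6.3,mg/kg,
Khansar,ash,P,1897.2,mg/kg,
Khansar,ash,Pb,3.8,mg/kg,
Khansar,ash,S,490,mg/kg,
Khansar,ash,Sb,<1,mg/kg,
Khansar,ash,Se,1.0,mg/kg,
Khansar,ash,Si,118.7,mg/kg,
Khansar,ash,Sn,1.0,mg/kg,
Khansar,ash,Sr,663.1,mg/kg,
Khansar,ash,Ti,17.0,mg/kg,
Khansar,ash,V,3.1,mg/kg,
Khansar,ash,Zn,26.0,mg/kg,
Borazjan,ash,Al,846.4,mg/kg,
Borazjan,ash,As,<50,ug/kg,
Borazjan,ash,B,248.6,mg/kg,
Borazjan,ash,Ba,56.3,mg/kg,
Borazjan,ash,Ca,70561,mg/kg,
Borazjan,ash,Cd,318,ug/kg,
Borazjan,ash,Ce,2.5,mg/kg,
Borazjan,ash,Co,1.3,mg/kg,
Borazjan,ash,Cr,2.3,mg/kg,
Borazjan,ash,Cu,17.5,mg/kg,
Borazjan,ash,Fe,1126.5,mg/kg,
Borazjan,ash,Hg,<50,ug/kg,
Borazjan,ash,K,49687,mg/kg,
Borazjan,ash,Mg,21759,mg/kg,
Borazjan,ash,Mn,129.3,mg/kg,
Borazjan,ash,Mo,4.7,mg/kg,
Borazjan,ash,Na,56909.0,mg/kg,
Borazjan,ash,Ni,5.9,mg/kg,
Borazjan,ash,P,2151.3,mg/kg,
Borazjan,ash,Pb,3.1,mg/kg,
Borazjan,ash,S,752,mg/kg,
Borazjan,ash,Sb,<1,mg/kg,
Borazjan,ash,Se,4.1,mg/kg,
Borazjan,ash,Si,127.4,mg/kg,
Borazjan,ash,Sn,5.7,mg/kg,
Borazjan,ash,Sr,1260.6,mg/kg,
Borazjan,ash,Ti,16.6,mg/kg,
Borazjan,ash,V,3.2,mg/kg,
Borazjan,ash,Zn,42.7,mg/kg,
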