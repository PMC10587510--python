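# Per-element inhalation reference dose (RfD, mg/kg/day) and cancer
# slope factor (CSF, (mg/kg/day)^-1); empty CSF = not determined (ND).
element,rfd_mg_kg_day,slope_factor
As,0.00012,150
Cd,0.00001,6.3
Co,0.0000057,9.8
Cr,0.00028,41
Cu,0.004,
Hg,0.000086,
Ni,0.02,
Pb,0.0035,0.042
Zn,0.3,1.5
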