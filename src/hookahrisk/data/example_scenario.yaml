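# EXAMPLE chronic-exposure scenario — assumed values, not study facts.
# A daily smoker of ~10 g tobacco over 30 years, lifetime-averaged
# (70 y x 365 d) as used for cancer endpoints.
IR_kg_per_day: 0.01
EF_days_per_year: 365
ED_years: 30
BW_kg: 70
AT_days: 25550
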