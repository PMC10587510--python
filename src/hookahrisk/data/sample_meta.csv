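# Study samples: three flavored (Maassel) and two traditional tobaccos.
sample_id,tobacco_type,label
Apple,maassel,Apple
Blueberry,maassel,Blueberry
Orange,maassel,Orange
Khansar,traditional,Khansar
Borazjan,traditional,Borazjan
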