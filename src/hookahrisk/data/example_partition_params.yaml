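# EXAMPLE partition parameters — assumed values, not measured ones.
# The study protocol (ashing at 600 C, a bowl of water, a tobacco charge)
# implies these three scale factors but does not report their magnitudes;
# any mass-balance run must state its own.
ash_yield: 0.25        # mass fraction of the charge left as ash
water_volume_l: 0.8    # bowl water per session, L
tobacco_mass_kg: 0.015 # tobacco charge burned per session, kg
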