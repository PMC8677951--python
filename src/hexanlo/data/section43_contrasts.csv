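on_key,off_key,printed_ratio,printed_difference,provenance
28M(NO2_NH2),28R(NO2_NH2),,8.77e3,section4.3.3
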