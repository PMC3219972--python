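CO2_ext
FA_ext
O2_ext
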