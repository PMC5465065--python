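freq_hz,z_mag_ohm
1,2700000
5,585400
10,306900
30,106700
50,72800
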