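test,intercept,slope,see
lm_immediate,6.883,0.595,2.7730
lm_delayed,4.810,0.680,3.1780
trails_a_seconds,0.589,0.598,0.1009
trails_b_seconds,0.656,0.643,0.1374
animals,8.410,0.623,4.0650
vegetables,4.464,0.687,3.2700
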