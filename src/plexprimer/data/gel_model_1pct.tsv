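# Log-size mobility model for 1% agarose: distance_mm = a - b*ln(size_bp + c)
# Fitted to ladder_1pct_agarose.tsv (least squares).
parameter	value
a	115.766461
b	13.172169
c	-1.191630
gel_percentage	1.0
lane_length_mm	60.0
min_size_bp	100
max_size_bp	3000
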