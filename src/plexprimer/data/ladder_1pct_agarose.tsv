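# Calibration ladder for a 1% agarose gel, 60 mm lane, ~90 min at 5 V/cm.
# Migration distance of standard ladder fragments, measured band-center to well.
# size_bp	distance_mm
100	55.3
150	49.8
200	46.1
300	40.6
400	36.9
500	34.0
700	29.5
1000	24.8
1500	19.5
2000	15.6
3000	10.3
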