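# Synthetic study-level calibration points for the P_isch -> P_sten link.
# These are NOT the five published studies' data (user-transcribed); they are
# plausible fabricated values with p_sten >= p_isch, one set per FFR threshold.
p_isch,p_sten,weight,threshold_label
0.10,0.22,120,0.75
0.25,0.38,200,0.75
0.40,0.55,150,0.75
0.60,0.72,180,0.75
0.80,0.90,100,0.75
0.14,0.22,120,0.80
0.30,0.38,200,0.80
0.46,0.55,150,0.80
0.65,0.72,180,0.80
0.84,0.90,100,0.80
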