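# Javelin liver-chip: two media chambers exchanged by a recirculating mixing
# flow; hepatocytes line one chamber only. q_mix is nominal (not published).
name: javelin
media_volume_ml: 1.30
cell_number: 2.15e+5
n_media_chambers: 2
recirculating: true
q_mix_ml_min: 0.5
sa_med_int_liver_cm2: 2.15
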