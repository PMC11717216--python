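# Dynamic42 chip: no published geometry; this preset is a PLACEHOLDER so the
# architecture can be selected and then overridden with measured values.
name: dynamic42
media_volume_ml: 1.0
cell_number: 2.0e+5
n_media_chambers: 1
recirculating: true
q_mix_ml_min: 1.0
sa_med_int_liver_cm2: 2.0
placeholder: true
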