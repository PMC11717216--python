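# 3D hepatocyte spheroids, static microplate (Hurel, low-cell-number study):
# 6e3 cells in 50 uL, no flow.
name: hurel1
media_volume_ml: 0.05
cell_number: 6.0e+3
n_media_chambers: 1
recirculating: false
q_mix_ml_min: 0.0
sa_med_int_liver_cm2: 0.06
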