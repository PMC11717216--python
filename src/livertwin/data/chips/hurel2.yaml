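# 3D hepatocyte spheroids, static microplate (Hurel, higher-cell-number
# study): 3e4 cells in 100 uL, no flow.
name: hurel2
media_volume_ml: 0.10
cell_number: 3.0e+4
n_media_chambers: 1
recirculating: false
q_mix_ml_min: 0.0
sa_med_int_liver_cm2: 0.30
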