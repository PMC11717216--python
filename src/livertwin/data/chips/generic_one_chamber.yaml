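# Generic static one-chamber culture: a neutral starting point for systems
# not in the library.
name: generic_one_chamber
media_volume_ml: 1.0
cell_number: 1.0e+5
n_media_chambers: 1
recirculating: false
q_mix_ml_min: 0.0
sa_med_int_liver_cm2: 1.0
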