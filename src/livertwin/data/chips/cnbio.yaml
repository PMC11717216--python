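# CnBio liver-chip: single recirculating on-chip media chamber.
# Cell number and media volume as reported for this system; the mixing flow
# and exchange area are nominal (flow does not enter a one-chamber model,
# and the exchange area is normally re-estimated from depletion data).
name: cnbio
media_volume_ml: 1.60
cell_number: 3.0e+5
n_media_chambers: 1
recirculating: true
q_mix_ml_min: 1.0
sa_med_int_liver_cm2: 3.0
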