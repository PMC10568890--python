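view,occupancy_bin,intervention,control,printed_p
immunisations,1,20,144,<0.01
immunisations,2,35,106,0.84
immunisations,3,26,66,0.32
immunisations,4,21,65,0.95
immunisations,5+,58,121,<0.01
screening_hc,1,16,40,0.96
screening_hc,2,18,55,0.45
screening_hc,3,18,46,0.97
screening_hc,4,16,56,0.21
screening_hc,5+,52,107,0.12
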