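period,arm,n_households,n_patients,n_consultations
before,intervention,144,295,1441
before,control,262,438,1713
during,intervention,152,301,1409
during,control,271,475,1762
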