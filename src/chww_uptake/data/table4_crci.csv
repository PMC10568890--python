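analysis,category,arm,n_households,mean_crci,sd_crci
main,immunisations,intervention,160,0.22,0.16
main,immunisations,control,502,0.15,0.18
main,screening_hc,intervention,120,0.20,0.32
main,screening_hc,control,304,0.11,0.26
main,overall,intervention,160,0.21,0.15
main,overall,control,502,0.15,0.19
sensitivity,immunisations,intervention,,0.37,0.27
sensitivity,immunisations,control,,0.32,0.29
sensitivity,screening_hc,intervention,,0.24,0.34
sensitivity,screening_hc,control,,0.19,0.34
sensitivity,overall,intervention,,0.29,0.25
sensitivity,overall,control,,0.26,0.27
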