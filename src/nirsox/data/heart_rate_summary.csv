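group,hr_baseline_max,hr_tilt_max,tilt_duration_min
POTS,76,123,30
control,66,85,30
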