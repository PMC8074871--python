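raw_feature,completion_rate_pct
Accel,87.0
Call log,94.6
Power state,94.3
Sociability call log,94.6
Accessibility log,87.2
GPS,93.0
Sleep,87.1
Sociability msg log,94.6
Ambient light,91.3
Heart,93.5
SMS log,94.6
Steps,96.9
Taps log,89.7
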