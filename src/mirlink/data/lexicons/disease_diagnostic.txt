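# Diagnosis-related disease aspect triggers.
biomarker
marker
predictor
profiler
prognostic
diagnosis
indicator
detection
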