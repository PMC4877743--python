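# Disease outcome / stage aspect triggers.
clinical outcome
outcome
disease free survival
disease-free survival
dfs
overall survival
survival
metastasis
sensitivity
prognosis
tumorgenicity
tumorigenicity
invasion
invasiveness
progression
aggressiveness
development
stage
recurrence
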