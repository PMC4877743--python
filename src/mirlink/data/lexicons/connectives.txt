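# Event-sequence connectives for the highly-informative scoring rule
# (verbs expanded to all inflections at load time).
contribute
result
cause
support
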