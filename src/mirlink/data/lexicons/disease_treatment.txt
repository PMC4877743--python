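# Treatment-related disease aspect triggers.
therapeutic
treatment
target
therapy
therapeutic target
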