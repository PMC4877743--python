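# Hedging / doubt triggers (verbs expanded to all inflections at load time).
might
could
suggest
propose
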