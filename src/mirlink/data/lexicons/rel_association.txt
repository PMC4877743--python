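# Association relation predicate triggers (verb lemma + preposition).
associate with
correlate with
link to
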