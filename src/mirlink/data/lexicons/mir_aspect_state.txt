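# State-type miR aspect triggers: mutation/methylation-like properties.
mutation
variant
polymorphism
methylation
hypermethylation
hypomethylation
silencing
knockdown
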