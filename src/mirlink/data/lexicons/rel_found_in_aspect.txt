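# Found-in relation triggers, aspect class: the miR aspect is inferred from the
# predicate ("miR-155 was overexpressed in gallbladder cancer").
overexpress in
highly express in
upregulate in
up-regulate in
downregulate in
down-regulate in
underexpress in
mutate in
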