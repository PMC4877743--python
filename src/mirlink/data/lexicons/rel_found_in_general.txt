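# Found-in relation triggers, general class: the miR aspect is stated in the
# miR entity itself ("high level of mir-155 was found in gallbladder cancer").
find in
detect in
increase in
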