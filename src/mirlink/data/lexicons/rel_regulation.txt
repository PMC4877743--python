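# Regulation relation predicate triggers.
regulate
promote
induce
elevate
target
enhance
increase
decrease
raise
upregulate
up-regulate
downregulate
down-regulate
modulate
cause
result in
interact with
block
mediate
suppress
inhibit
repress
overexpress
restore
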