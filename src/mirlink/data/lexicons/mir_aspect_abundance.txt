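# Abundance-type miR aspect triggers (noun-phrase heads).
level
expression
regulation
overexpression
underexpression
upregulation
up-regulation
downregulation
down-regulation
restoration
abundance
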