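# Verb <-> nominalization pairs: "verb: nominal[, nominal...]".
regulate: regulation, regulator
express: expression
inhibit: inhibition, inhibitor
suppress: suppression, suppressor
repress: repression
methylate: methylation
induce: induction
promote: promotion
mediate: mediation
restore: restoration
activate: activation
elevate: elevation
modulate: modulation
interact: interaction
detect: detection
treat: treatment
develop: development
involve: involvement
contribute: contribution
participate: participation
associate: association
correlate: correlation
upregulate: upregulation
up-regulate: up-regulation
downregulate: downregulation
down-regulate: down-regulation
overexpress: overexpression
silence: silencing
target: targeting
increase: increase
decrease: decrease
block: blockade
cause: cause
support: support
result: result
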