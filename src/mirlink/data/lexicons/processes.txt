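# Cellular-process dictionary for linking-entity detection.
# Morphological derivatives (-sion/-tion/-sis/-or/-er/-ment) are matched by rule;
# this list covers common processes the suffix rules miss.
apoptosis
proliferation
cell proliferation
growth
cell growth
migration
motility
cell motility
invasion
angiogenesis
differentiation
transition
epithelial-mesenchymal transition
emt
pathway
signaling
cell cycle
autophagy
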