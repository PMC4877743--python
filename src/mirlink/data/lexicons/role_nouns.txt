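# Role nouns accepted as is-a relation themes.
tumor suppressor
tumour suppressor
tumor suppressor gene
oncogene
oncomir
regulator
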