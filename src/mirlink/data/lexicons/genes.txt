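# Bundled fallback gene lexicon (used when no sidecar annotations are given).
e-cadherin
cdh1
itgb3
camsap1
srsf9
ctbp1
cox-2
bcl-2
bcl2
pten
stat3
pias3
ubash3b
foxo1
mthfd2
vimentin
kras
tp53
myc
egfr
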