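# Bundled fallback disease lexicon (used when no sidecar annotations are given).
osteosarcoma
esophageal squamous cell carcinoma
escc
pancreatic cancer
breast cancer
breast carcinoma
colorectal cancer
gastric cancer
glioma
glioblastoma
melanoma
gallbladder cancer
bladder cancer
bladder carcinoma
laryngeal squamous cell carcinoma
squamous cell carcinoma
oral squamous cell carcinoma
oscc
pulmonary arterial hypertension
liver fibrosis
hepatocellular carcinoma
chronic myelogenous leukemia
leukemia
lymphoma
lung cancer
non-small cell lung cancer
prostate cancer
ovarian cancer
epithelial ovarian cancer
eoc
triple negative breast cancer
dementia
diabetes
cardiovascular disease
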