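# Neuroendocrine-tumor-associated genes used for top-tier prioritization.
# Editable: one gene symbol per line; override with --net-genes or config.
MEN1
DAXX
ATRX
EPAS1
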