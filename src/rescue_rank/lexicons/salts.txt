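# Salt lexicon for the summarizer's salt-type column.
# Order is priority: the first entry found in a step's text wins.
NaCl
KCl
(NH4)2SO4
ammonium sulfate
LiCl
MgCl2
CaCl2
MgSO4
sodium chloride
potassium chloride
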