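# Purification vocabulary: a sentence mentioning any of these terms is
# considered protocol text by the rule-based extraction backend.
# One term per line; matching is case-insensitive substring.
column
resin
buffer
elution
eluted
elute
imidazole
dialysis
dialyzed
dialysed
his-tag
his tag
polyhistidine
size-exclusion
size exclusion
gel filtration
superdex
sephacryl
histrap
ni-nta
ni sepharose
nickel
talon
chromatography
lysis
lysed
sonicated
sonication
homogenized
wash buffer
washed with
equilibrated
purified
purification
centrifuged at
flow-through
glutathione
strep-tactin
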