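# Step-boundary lexicon for the summarizer: a sentence containing one of
# these starts a new purification step; the matched text becomes the
# step label. Order is priority within a sentence (earliest match wins;
# on a tie at the same position the earlier lexicon entry wins).
lysis
lysed
lyse
sonicated
homogenized
equilibration
equilibrated
binding
bound
loaded
histrap
ni-nta
ni sepharose
nickel
talon
washed
wash
elution
eluted
dialysis
dialyzed
dialysed
cleavage
cleaved
size-exclusion
size exclusion
gel filtration
superdex
sephacryl
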