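# Buffer-supplement lexicon: stabilizing additives recognized by the
# summarizer. One term per line; case-insensitive substring match.
protease inhibitor cocktail
protease inhibitor
lysozyme
glycerol
DTT
TCEP
β-mercaptoethanol
beta-mercaptoethanol
2-mercaptoethanol
CHAPS
DDM
Triton X-100
Tween 20
EDTA
PMSF
benzonase
DNase
arginine
trehalose
sucrose
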