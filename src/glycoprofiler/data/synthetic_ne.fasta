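>NE_SYNTH synthetic stand-in, neutrophil elastase unprocessed chain (267 aa)
AGVQRAEGLAGVQRAEGLAGVQRAEGLAGVQRAEGLAGVQRAEGLAGVQRAEGLAGVQRA
EGLAGVQRAEGLAGVQRAEGLAGVQRAEGLAGVQRAEGLAGVQRAEGLAGVQRALAGVQR
AEGNVTKERAEGLGLAGVQRAEGLAGVQRAEGLAGVQRAEGKALAGVQRAEGNVTDKRAE
GLVQRAEGLAGVQRAEGLAGVQRAEGLAGVQRAEGLAGVQRAEGLAGVQRAEGLAGVQRA
EGLAGVQRAEGLAGVQRAEGLAGVQRA
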