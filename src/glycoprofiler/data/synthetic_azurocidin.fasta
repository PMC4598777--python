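>AZU_SYNTH synthetic stand-in, azurocidin unprocessed chain (251 aa)
AGVQRAEGLAGVQRAEGLAGVQRAEGLAGVQRAEGLAGVQRAEGLAGVQRAEGLAGVQRA
EGLAGVQRAEGLAGVQRAEGLAGVQRAEGLAGVQRAEGLAGVQRAEGLAGVQRAEGLAGV
QRAEGNVTIARAEGLAGVQRAEGLAGVQRAEGLAGVQRAEGLAGVQRAEGNVTRERAEGL
AGVQRAEGLAGVQRAEGLAGVQRAEGLAGVQRAEGLAGVQRAEGLAGVQRAEGLAGVQRA
EGLAGVQRAEG
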