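>NCG_SYNTH synthetic stand-in, neutrophil cathepsin G unprocessed chain (255 aa)
MQPLLLLLAFLLPTGAGAGEIIGGRESRPHSRPYMAYLQIQSPAGQSRCGGFLVREDFVL
TAAHCWGSNINVTLGAHNIQRRENTQQHITARRAIRHPQYNQRTIQNDIMLLQLSRRVRR
NRNVNPVALPRAQEGLRPGTLCTVAGWGRVSMRRGTDTLREVQLRVQRDRQCLRIFGSYD
PRRQICVGDRRERKAAFKGDSGGPLLCNNVAHGIVSYGKSSGVPPEVFTRVSSFLPWIRT
TMRSFKLLDQMETPL
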