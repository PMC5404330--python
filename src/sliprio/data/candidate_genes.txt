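# Literature candidate genes for speech, language and reading disorders
CMIP
ATP2C2
CNTNAP2
NFXL1
FOXP1
FOXP2
DYX1C1
KIAA0319
DCDC2
ROBO1
SRPX2
GRIN2A
GRIN2B
ERC1
SETBP1
CNTNAP5
DOCK4
SEMA6D
AUTS2
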