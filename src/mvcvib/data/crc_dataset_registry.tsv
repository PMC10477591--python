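name	n_total	n_control	n_disease
Colorectal (CRC1)	121	73	48
Colorectal-EMBL (CRC2)	199	103	96
Early-colorectal-EMBL (CRC3)	96	52	44
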