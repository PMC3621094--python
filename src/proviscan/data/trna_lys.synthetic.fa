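>Lys1_2
TGGCGCCCTACGCTGTAC
>Lys3
TGGCGCCCGAACAGGGAC
>LysAlt
TGGGTGGGGCACAGGGAC
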