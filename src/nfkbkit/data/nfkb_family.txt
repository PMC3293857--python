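# The five NF-kB family members (UniProt entry-name style IDs)
TF65
NFKB1
NFKB2
REL
RELB
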