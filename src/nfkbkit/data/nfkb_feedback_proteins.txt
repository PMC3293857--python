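# Published 49-member feedback set: proteins that sit in the NF-kB upstream
# activation interactome and whose genes are transcriptionally regulated by
# NF-kB itself (UniProt entry-name style IDs, alphabetical).
ANDR
BCL3
BIRC4
BLNK
BTK
CAV1
CFLAR
EGR1
ELF3
ERBB2
GCR
HS90A
IKBA
IKBE
IKBZ
IL2RA
IL32
IRF1
IRF2
KISS1
LYSC
MYC
NFKB1
NFKB2
NOD2
NUAK2
OLR1
P53
PRGR
PSA2
PSB9
PTEN
REL
RELB
RIPK2
TCAM1
TERT
TGM2
TIFA
TLR2
TLR9
TNAP3
TNF15
TNIP1
TNIP3
TRAF1
TRAF2
TWST1
VIME
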