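# Demo RBP PWM panel for tests and worked examples.  These are
# illustrative position-frequency models built from each protein's
# published binding preference (ELAVL1/HuR: AU-rich elements; RBMX:
# single-stranded CC[A/C]-rich motifs; SFRS1: purine-rich exonic
# enhancers), not matrices exported from any database.
>ELAVL1
A  0.10 0.05 0.05 0.70 0.05 0.10 0.10
C  0.05 0.05 0.05 0.10 0.05 0.05 0.05
G  0.05 0.05 0.05 0.10 0.05 0.05 0.05
U  0.80 0.85 0.85 0.10 0.85 0.80 0.80
>RBMX
A  0.10 0.05 0.45 0.10 0.05 0.10
C  0.75 0.85 0.45 0.75 0.85 0.75
G  0.10 0.05 0.05 0.10 0.05 0.10
U  0.05 0.05 0.05 0.05 0.05 0.05
>SFRS1
A  0.15 0.60 0.10 0.15 0.60 0.15
C  0.10 0.10 0.10 0.10 0.10 0.10
G  0.70 0.20 0.75 0.70 0.20 0.70
U  0.05 0.10 0.05 0.05 0.10 0.05
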