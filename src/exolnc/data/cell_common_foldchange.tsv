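# Common lncRNAs enriched in the cells (depleted from exosomes) of the
# four prostate cancer cell lines; signed fold change, negative = up in
# the cell.  Values as printed on the expression array report.
Gene name	VCaP	LNCaP	DU145	PC3	type
AK098134	-48.6	-3.5	-3.5	-14.1	intergenic
uc.63-	-18.6	-3.4	-3.4	-9.6	intron sense-overlapping
uc004exm.2	-7.2	-2.1	-2.1	-22.2	intergenic
ENST00000513351	-23.2	-2.4	-2.4	-4.3	intergenic
BC008292	-10.9	-2.7	-2.7	-2.7	bidirectional
BC131500	-4.1	-5.0	-5.0	-2.0	intronic antisense
AK125090	-6.5	-2.6	-2.6	-3.5	intergenic
ENST00000366160	-3.0	-3.4	-3.4	-5.2	intergenic
NR_002998	-3.5	-2.0	-2.0	-7.2	intron-sense overlapping
G43604	-4.0	-3.2	-3.2	-2.9	natural antisense
NR_024413	-4.1	-2.0	-2.0	-3.9	intron-sense overlapping
uc003hqg.1	-5.3	-2.1	-2.1	-2.4	intronic antisense
uc003eub.2	-3.6	-2.0	-2.0	-4.1	intergenic
NR_024334	-2.7	-3.3	-3.3	-2.5	natural antisense
uc003nov.3	-3.1	-2.6	-2.6	-2.4	intergenic
ENST00000429037	-2.6	-2.4	-2.4	-2.6	intergenic
HIT000097222	-2.7	-2.1	-2.1	-3.3	natural antisense
AK097323	-2.0	-2.7	-2.7	-2.2	natural antisense
NR_002836	-2.2	-2.4	-2.4	-2.3	intergenic
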