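# Common lncRNAs enriched in the exosomes of four prostate cancer cell
# lines; signed fold change (exosome vs cell) per line, positive = up
# in exosome.  Values as printed on the expression array report.
Gene name	VCaP	LNCaP	DU145	PC3	type
ENST00000501280	62.0	21.4	21.4	14.7	bidirectional
uc010bys.1	28.7	11.0	11.0	14.6	intergenic
uc001qgn.1	50.0	5.4	5.4	3.0	intronic antisense
ENST00000499690	15.4	16.2	16.2	8.5	intronic antisense
ENST00000453968	48.5	2.5	2.5	2.3	intergenic
G36642	46.0	3.0	3.0	2.2	intronic antisense
AK055500	39.1	3.5	3.5	6.1	intergenic
HIT000070262	44.2	2.7	2.7	2.1	natural antisense
ENST00000452932	11.8	9.5	9.5	7.7	intergenic
chr13:38754175-38773200+	25.6	3.7	3.7	2.8	intergenic
nc-HOXB1-156-	7.4	8.4	8.4	2.6	intergenic
ENST00000471393	18.5	2.3	2.3	3.5	intergenic
ENST00000412906	20.0	2.2	2.2	2.1	intronic antisense
ENST00000392478	3.7	6.2	6.2	2.0	intronic antisense
AY927529	7.0	2.6	2.6	5.8	exon-sense overlapping
ENST00000426885	5.8	3.3	3.3	4.5	intergenic
AK123811	2.3	3.7	3.7	4.9	intergenic
ENST00000402340	5.7	2.3	2.3	3.7	intergenic
ENST00000509526	4.9	2.3	2.3	3.4	intergenic
ENST00000412347	4.1	2.5	2.5	3.0	intergenic
chr9:137160729-137173954-	3.8	2.4	2.4	2.8	intergenic
ENST00000411341	3.3	2.3	2.3	3.2	intergenic
ENST00000430245	2.8	2.9	2.9	2.4	intronic antisense
ENST00000508864	3.9	2.4	2.4	2.1	intergenic
uc001upm.2	2.2	2.0	2.0	4.3	intergenic
ENST00000500478	3.2	2.2	2.2	2.3	intergenic
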