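; Mature miRNA fixture panel for the seed-matching examples and tests.
; Well-characterised miRNAs (let-7 family, miR-17 family, miR-149-3p,
; miR-328-5p) carry their known mature sequences.  Entries marked
; "synthetic flank" are recently annotated miRNAs whose full mature
; sequence is not bundled: the seed hexamer (positions 2-7) is the one
; implied by their annotated seed family (the GGGAGG miR-149-3p seed
; family, whose reverse complement is CCUCCC) while flanking bases are
; synthetic placeholders.  Only the seed participates in matching.
>hsa-let-7a-5p
UGAGGUAGUAGGUUGUAUAGUU
>hsa-let-7b-5p
UGAGGUAGUAGGUUGUGUGGUU
>hsa-let-7c-5p
UGAGGUAGUAGGUUGUAUGGUU
>hsa-let-7d-5p
AGAGGUAGUAGGUUGCAUAGUU
>hsa-let-7e-5p
UGAGGUAGGAGGUUGUAUAGUU
>hsa-let-7g-5p
UGAGGUAGUAGUUUGUACAGUU
>hsa-let-7i-5p
UGAGGUAGUAGUUUGUGCUGUU
>hsa-miR-17-5p
CAAAGUGCUUACAGUGCAGGUAG
>hsa-miR-18a-5p
UAAGGUGCAUCUAGUGCAGAUAG
>hsa-miR-20a-5p
UAAAGUGCUUAUAGUGCAGGUAG
>hsa-miR-20b-5p
CAAAGUGCUCAUAGUGCAGGUAG
>hsa-miR-93-5p
CAAAGUGCUGUUCGUGCAGGUAG
>hsa-miR-106a-5p
AAAAGUGCUUACAGUGCAGGUAG
>hsa-miR-106b-5p
UAAAGUGCUGACAGUGCAGAU
>hsa-miR-149-3p
AGGGAGGGACGGGGGCUGUGC
>hsa-miR-328-5p
GGGGGGGCAGGAGGGGCUCAGGG
>hsa-miR-7106-5p synthetic flank
AGGGAGGCAGAGGCAGGUGCAG
>hsa-miR-6883-5p synthetic flank
AGGGAGGGGCUGGGCAGGAGGA
>hsa-miR-6799-5p synthetic flank
AGGGAGGGAGGCAGGAGCCUGC
>hsa-miR-6785-5p synthetic flank
AGGGAGGGGCGGGAGCCAGGAC
>hsa-miR-4728-5p synthetic flank
UGGGAGGGGAGAGGCAGCAAGC
>hsa-miR-6887-5p synthetic flank
AGGGAGGCGCAGGCACCUGCAG
>hsa-miR-6885-5p synthetic flank
AGGGAGGAGGCUGGGCCAGGAU
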