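# PCR-RFLP locus definitions for the five typed SNPs.
# Each locus lists the allele pair, the allele whose amplicon carries the
# enzyme recognition site ("cut_allele"), and one entry per primer set
# with the amplicon length and the expected digest fragment sizes in bp.
# The Chr21 alternative amplicon is recorded exactly as published: its
# digest fragments sum to 423 bp against a 410 bp amplicon, a 13 bp
# discrepancy that validate_locus_definition flags rather than corrects.
loci:
  - locus_name: Chr1
    snp_id: rs21953123
    alleles: [C, T]
    cut_allele: C
    enzyme: HpyCH4II
    recognition_site: ACTGT
    primer_sets:
      - label: original
        pcr_length: 311
        digest_fragments: [228, 83]
      - label: alternative
        pcr_length: 417
        digest_fragments: [260, 157]
  - locus_name: Chr10
    snp_id: rs22078677
    alleles: [A, C]
    cut_allele: C
    enzyme: BanI
    recognition_site: GGCACC
    primer_sets:
      - label: original
        pcr_length: 374
        digest_fragments: [19, 355]
      - label: alternative
        pcr_length: 161
        digest_fragments: [19, 142]
  - locus_name: Chr15
    snp_id: rs22422063
    alleles: [C, A]
    cut_allele: C
    enzyme: NciI
    recognition_site: CCCGG
    primer_sets:
      - label: original
        pcr_length: 375
        digest_fragments: [196, 179]
      - label: alternative
        pcr_length: 443
        digest_fragments: [227, 216]
  - locus_name: Chr21
    snp_id: rs22923291
    alleles: [G, A]
    cut_allele: G
    enzyme: Fnu4HI
    recognition_site: GCTGC
    primer_sets:
      - label: original
        pcr_length: 349
        digest_fragments: [310, 39]
      - label: alternative
        pcr_length: 410
        digest_fragments: [384, 39]
  - locus_name: Chr37
    snp_id: rs24025150
    alleles: [G, A]
    cut_allele: G
    enzyme: HpaII
    recognition_site: CCGG
    primer_sets:
      - label: original
        pcr_length: 374
        digest_fragments: [28, 346]
      - label: alternative
        pcr_length: 133
        digest_fragments: [28, 105]
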