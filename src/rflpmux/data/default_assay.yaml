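# Default multiplex PCR-RFLP assay layout.
#
# Apparent fragment sizes (bp) after MnlI + HindIII co-digestion on a 5-dye
# capillary setup.  Channel colours follow the G5 filter convention:
# PET=red, 6-FAM=blue, VIC=green, NED=black (orange = size standard).
#
# F5 (FV Leiden): MnlI cuts the wild-type allele to 92 bp; the variant
# destroys that site and yields 129 bp.  The 289 bp uncut amplicon must
# disappear entirely after digestion (internal MnlI control).
# F2 (G20210A): HindIII cuts the variant allele to 226 bp via a mutagenic
# primer; wild type stays at the 246 bp amplicon length.
# FGA_intron1: HindIII digestion control — mandatory site, 339 bp uncut must
# vanish, 276 bp cut product must appear.
# FGA / SE33 STRs: identity and contamination monitoring.  The FGA STR
# amplicon contains an MnlI site; sizes are post-MnlI (undigested alleles
# run 56 bp larger).

fragment_rules:
  - {locus_id: F5, allele_label: wt, apparent_size: 92.0, dye: red,
     must_be_absent_after_digestion: false}
  - {locus_id: F5, allele_label: variant, apparent_size: 129.0, dye: red,
     must_be_absent_after_digestion: false}
  - {locus_id: F5, allele_label: uncut, apparent_size: 289.0, dye: red,
     must_be_absent_after_digestion: true}
  - {locus_id: F2, allele_label: wt, apparent_size: 246.0, dye: red,
     must_be_absent_after_digestion: false}
  - {locus_id: F2, allele_label: variant, apparent_size: 226.0, dye: red,
     must_be_absent_after_digestion: false}
  - {locus_id: FGA_intron1, allele_label: control_uncut, apparent_size: 339.0,
     dye: black, must_be_absent_after_digestion: true}
  - {locus_id: FGA_intron1, allele_label: control_cut, apparent_size: 276.0,
     dye: black, must_be_absent_after_digestion: false}

str_loci:
  - locus_id: FGA
    dye: green
    repeat_unit: 4
    min_repeats: 14
    max_repeats: 50.2
    size_at_min_repeats: 92.0
    observed_size_min: 92.0
    observed_size_max: 238.0
    uncut_size_shift: 56.0
  - locus_id: SE33
    dye: blue
    repeat_unit: 4
    min_repeats: 4.2
    max_repeats: 39
    size_at_min_repeats: 279.0
    observed_size_min: 279.0
    observed_size_max: 417.0
    uncut_size_shift: 0.0

thresholds:
  allele_call_rfu: 150.0      # 3 x noise ceiling
  noise_ceiling_rfu: 50.0
  saturation_rfu: 32000.0
  stutter_max_fraction: 0.11  # stutter mean + 2 SD
  het_ratio_min_f5: 0.49      # het ratio mean - 2 SD
  het_ratio_min_f2: 0.49
  str_het_ratio_min: 0.30
  size_match_tol: 1.0
  str_bin_tol: 0.5
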