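# Methods

This note documents the models, rules and numerical choices behind
`rflpmux`, and what the in-silico validation does and does not demonstrate.

## 1. Assay model

The assay is declarative: an `AssayConfig` lists every expected fragment
(locus, allele, dye channel, apparent size), the two STR locus definitions,
and the interpretation thresholds. Apparent sizes are instrument-reported
sizes and are treated as exact configured constants — no mobility model maps
them to true sequence lengths. Fixed fragments are matched within ±1.0 bp
(single-base resolution of POP7 capillary electrophoresis); STR peaks are
binned within ±0.5 bp.

The packaged default encodes the published layout: *F5* wt 92 / variant 129 /
uncut 289 bp (red), *F2* wt 246 / variant 226 bp (red), *FGA* intron-1
control cut 276 / uncut 339 bp (black), FGA STR (green) and SE33 STR (blue).
Where the source material disagrees with itself we fixed one value and made
it configurable: the cut control is 276 bp (275 also appears in the
original figure caption), and the allele-call threshold defaults to 150 RFU
(3× noise; 250 RFU is quoted elsewhere as a conservative instrument-side
detection cutoff).

### STR ladders

Allele naming follows the forensic convention: allele *n.p* means *n* full
tetranucleotide repeats plus *p* extra bases (*p* ∈ {1,2,3}), so the size
map is `size(n.p) = anchor + 4·(n − n_min) + (p − p_min)`. Because
microvariants cover every integer base, any size inside the observed window
bins to some allele; "off-ladder" means outside the window. The windows are
derived from this linear map anchored at the smallest allele (FGA: 92–238 bp
for 14–50.2 repeats; SE33: 279–417 bp for 4.2–39 repeats). The published
upper window ends (243 and 421 bp) are a few bp larger than any linear map
through the published repeat ranges allows; we attribute the difference to
apparent-size/mobility effects, which are out of scope, and keep the
self-consistent ladder values. The FGA STR amplicon carries an MnlI site
upstream of the repeat; undigested FGA alleles run +56 bp, which the
simulator reproduces in digestion-failure mode.

## 2. In-silico digestion

`digest` models enzymes as an IUPAC recognition motif plus per-strand cut
offsets (MnlI: CCTC 7/6, type IIS; HindIII: A^AGCTT). Only top-strand cut
coordinates are reported — capillary electrophoresis sees denatured
5'-labelled single strands, so the labelled-strand scission determines the
sized fragment. Bottom-strand recognition events are mapped to their
top-strand cut coordinate (for MnlI this lands 6 nt *upstream* of the
reverse motif). Cuts whose offset falls outside the sequence are dropped
silently. Fragments always tile the input exactly (conservation is a tested
invariant, and the site finder is verified against a brute-force
both-strand scan). Full amplicon sequences for the assay are not published,
so the engine is validated on constructed and random sequences only.

## 3. Calling rules

Per sample, in order:

1. **Digestion gates.** MnlI valid ⇔ no ≥150 RFU peak at 289 bp; HindIII
   valid ⇔ no peak at 339 bp *and* a ≥150 RFU peak at 276 bp. An invalid
   enzyme forces `no_call` at its loci: this is load-bearing for *F2*,
   whose wild-type fragment *is* the uncut amplicon (246 bp), so wt/wt and
   digestion failure are distinguishable only through the control. The FGA
   STR (an MnlI product) is likewise not called when MnlI failed.
2. **Biallelic loci.** Fragment presence above 150 RFU determines the
   genotype; heterozygotes carry `ratio = var_height / wt_height`
   (variant-over-wild-type, one-sided lower bound only). Ratio < 0.49 ⇒
   `RATIO_LOW_*` and verdict RETEST.
3. **STR loci.** Candidate peaks are processed tallest-first. A peak one
   repeat below a taller accepted allele is *stutter* if ≤ 11 % of its
   parent, *suspected contamination* if in (11 %, 30 %), and a genuine
   adjacent-repeat sister allele if ≥ 30 %. A second allele candidate at
   any position must also reach 30 % of the tallest peak — a lone 5 %
   companion peak is a contaminant allele, not a heterozygote. Remaining
   peaks are extra (third allelic peak / off-ladder).

The 30 % sister-peak bound (`str_het_ratio_min`) is our design choice where
the published rules are silent: taken literally, "any stutter-position peak
above 11 % is contamination" would misclassify real adjacent-repeat
heterozygotes (sister ratios cluster near 1), while accepting any
stutter-position peak as an allele would hide contamination under
homozygotes. 30 % sits several SDs above the stutter cap and several SDs
below realistic heterozygote balance, and is configurable.

Verdict: FAIL on digestion failure; RETEST on any other flag; PASS only
with an empty flag set. Raising the call threshold can only remove alleles
(tested monotonicity), and all calls are invariant under a common height
rescaling below saturation.

## 4. Contamination, identity, RMP

Three criteria, each sufficient: `EXTRA_ALLELE` (unexplained or off-ladder
STR peak), `STUTTER_EXCESS` (stutter-position fraction above the cap), and
`RATIO_IMBALANCE` (delegated to the caller's 0.49 flags rather than
recomputed — a low ratio triggers a re-test even without an extra STR
peak). A contaminant sharing all four STR alleles, or hiding entirely under
allele and stutter positions, is undetectable by construction; this blind
spot is inherent to the design and documented, not patched. No quantitative
mixture-ratio estimator is provided.

Identity comparison requires equal allele multisets at every co-called STR
locus (single peaks are read as homozygotes); no co-called locus yields
*incomparable*, distinct from a mismatch. The random-match probability is
the Hardy-Weinberg product Π (p² or 2pq) with an optional frequency floor
(default 10⁻³) for alleles missing from a partial table; no population
substructure correction is applied. The shipped frequency table
(`data/synthetic_str_frequencies_demo.csv`) is a **synthetic demo fixture**
shaped like forensic tables (FGA moderately, SE33 highly polymorphic); with
it the most-common-genotype RMP is ~8 × 10⁻⁴, the right order of magnitude
for this locus pair.

## 5. Simulator

The generator emulates, per sample: log-normal per-locus base heights
(median 8,000 RFU, log-sd 0.30 — mid-range of the 250–32,000 RFU band the
instrument reports, chosen once as typical of a healthy run); heterozygote
ratio draws N(0.61, 0.06²) for *F5* and N(0.67, 0.09²) for *F2*, truncated
to (0, 1.5); sister-allele imbalance as a log-normal factor (log-sd 0.10,
i.e. sister ratios mostly 0.8–1.25); stutter fractions N(7.6 %, 1.8 %²) for
FGA and N(7.6 %, 1.6 %²) for SE33, truncated at 0, peaks below 1 RFU
dropped; Poisson(3) background noise peaks uniform below 50 RFU; saturation
clipping at 32,000 RFU after summing coincident peaks. STR genotypes are
Hardy-Weinberg draws from the frequency table; F5/F2 states are fixed per
study design or drawn from population carrier frequencies (variant allele
frequencies 0.025 / 0.011). Contaminant peak heights scale linearly with
the ng:ng ratio; PCR competition and preferential amplification of short
alleles are acknowledged bench phenomena but not modelled. A single
`numpy.random.Generator` drives every draw, so a fixed seed reproduces the
peak table byte-exactly through the CSV writer.

**What it does not emulate:** continuous electropherogram traces, dye
pull-up, size-calling error (sizes are exact by construction), allele
dropout, degraded DNA, and n+1/n−2 stutter. Passing the in-silico studies
therefore shows the *decision logic* is correct under the assay's validated
statistical behaviour; it does not re-demonstrate the wet-lab accuracy of
the published 62-clinical-sample study, which requires real DNA.

## 6. Validation-study replicas

* **Concordance** — 62 samples (31 wt/wt, 16 *F5* het, 14 *F2* het, 1 *F5*
  hom — the published cohort's n column, whose per-row concordance
  denominators are internally inconsistent; we reproduce the headline
  62/62). Expected: 100 % genotype concordance under clean defaults.
* **Mixtures** — 30 two-person mixtures at 1:10 and 1:20 (ng:ng), variant
  states drawn from the published donor pool proportions (14 wt/wt : 5 *F5*
  het : 3 *F2* het; the pool's 22 donors generated 30 mixtures), STR
  genotypes drawn independently from the demo table, contaminant redrawn on
  a full-profile collision (mixtures are between distinct individuals).
  Expected: 100 % detection at both ratios, and detection monotone
  non-decreasing over a 1:100 → 1:5 sweep under common random numbers.
* **Calibration** — empirical mean ± sd of called het ratios and
  stutter-position fractions recover the configured moments (stutter
  statistics include above-cap stutter-position peaks, so the estimate is
  not truncated at the 11 % rule).

Problem sizes (62, 30, and 1,000–2,000 samples for moment recovery) are the
study's own designs or standard law-of-large-numbers choices; each study
runs in seconds. Stutter-cap multiplier k defaults to 2 (mean + 2 SD = 11 %;
a mean + 3 SD variant also appears in the source and is configurable via
`stats.threshold_from_moments`).

## 7. Statistics

Thresholds are mean + k·SD with printing-convention rounding (2 decimals
for ratios, integer percent for stutter). Proportion CIs use the Wilson
score interval with z fixed at 1.959964, which reproduces the published
0.89 lower bound at 30/30 (Clopper-Pearson gives 0.88); the closed form
n/(n+z²) at full success is the test oracle, and statsmodels is the
independent cross-check. Sensitivity/specificity follow the both-locus
concordance definition (a carrier is concordant only if both F5 and F2
match). The published accuracy-table CIs whose denominators cannot be
reconstructed from the inconsistent cohort counts are not reproduced; only
the self-consistent n = 30 interval is.
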