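# rflpmux

Computational interpretation of a multiplex fluorescent **PCR-RFLP assay**
for the two thrombophilia variants that require DNA testing — **FV Leiden**
(*F5* c.1601G>A, p.Arg534Gln) and ***F2* G20210A** (*F2* c.\*97G>A) — with
built-in digestion control, STR-based identity monitoring and contamination
detection.

It is written for molecular-diagnostics labs running this kind of assay on a
capillary sequencer: it takes the peak tables exported by fragment-analysis
software (sample, dye, apparent size in bp, height in RFU) and returns
genotypes with QC verdicts. It also ships an in-silico restriction digestion
engine, a calibrated peak-table simulator, and the validation statistics
needed to qualify the assay — so the entire validation study can be replayed
on a laptop with no instrument data.

## The assay in brief

One multiplex PCR co-amplifies five targets, digested overnight with MnlI +
HindIII and sized on a 5-dye capillary setup:

| target | dye | fragments (bp) | reading |
|---|---|---|---|
| *F5* exon 10 | red | wt 92 / variant 129 / uncut 289 | FV Leiden destroys an MnlI site (CCTC) |
| *F2* 3'UTR | red | wt 246 / variant 226 | a mutagenic primer turns G20210A into a HindIII site (AAGCTT) |
| *FGA* intron 1 | black | cut 276 / uncut 339 | mandatory HindIII site — digestion control |
| FGA STR | green | 92–238 (alleles 14–50.2) | identity + contamination |
| SE33 STR | blue | 279–417 (alleles 4.2–39) | identity + contamination |

Interpretation rules, all derived from validated bench moments and all
configurable:

- allele call threshold **150 RFU** (3× the ≤50 RFU fluorescence noise);
- a surviving 289 or 339 bp peak ⇒ **digestion failure**, no genotype is
  ever emitted for the affected enzyme's loci;
- heterozygote variant/wt height ratios are distributed 0.61 ± 0.06 (*F5*)
  and 0.67 ± 0.09 (*F2*); a ratio below **mean − 2 SD = 0.49** triggers a
  re-test;
- STR stutter (one repeat unit below an allele) runs 7.6 ± 1.8 % of the
  parent height; a stutter-position peak above **mean + 2 SD = 11 %** is
  suspected contamination;
- contamination is flagged by any of three criteria: an **extra STR
  allele**, a **stutter exceedance**, or a **ratio imbalance**;
- identity between runs is checked by comparing the FGA+SE33 profiles; the
  Hardy-Weinberg **random-match probability**
  `RMP = Π_loci (p² or 2pq)` quantifies their discriminating power
  (~5 × 10⁻⁴ for common genotypes).

## Worked example

Simulate one FV-Leiden heterozygote, call it, and screen it:

```bash
rflpmux simulate --n 1 --seed 42 \
    --genotype "F5=het,F2=wt,FGA=21/24,SE33=17/28.2" --out peaks.csv
rflpmux call peaks.csv --out reports.csv
cat reports.csv
```

```
Sample,Run,F5,F2,FGA,SE33,RatioF5,RatioF2,Flags,Verdict
S001,sim-seed42,het,wt,21/24,17/28.2,0.532,,,PASS
```

The sample is heterozygous FV Leiden (92 + 129 bp peaks, height ratio 0.53 —
above the 0.49 re-test bound), wild type for *F2* G20210A (246 bp only, with
the 276 bp control confirming HindIII cut), and its STR profile is FGA 21/24,
SE33 17/28.2 with clean stutters. QC screens:

```bash
rflpmux qc contamination reports.csv   # -> S001  clean
rflpmux qc rmp reports.csv             # -> S001  0.000495
```

i.e. no contamination criterion fires, and roughly 1 random person in 2,000
would share this two-locus STR profile.

Other entry points: `rflpmux digest amplicons.fa --enzymes MnlI,HindIII`
(in-silico digestion), `rflpmux simulate study --name mixture_1to20`
(validation-study replicas), `rflpmux qc identity`, `rflpmux stats
concordance`, `rflpmux config show-default`. Every command that writes a
file also writes a `*.manifest.json` (seed, config hash, version) so runs
can be reproduced bit-exactly. The same functionality is available as a
library (`rflpmux.caller.call_sample`, `rflpmux.simulator.synthesize`, …).

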