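"""Per-sample genotype calling with digestion-control validation.

The decision procedure mirrors how a fragment-analysis operator reads the
electropherogram:

1. **Digestion controls first.**  A surviving 289 bp peak (uncut F5
   amplicon) invalidates the MnlI digest; a surviving 339 bp peak or a
   missing 276 bp cut product (FGA intron-1 control) invalidates the
   HindIII digest.  A locus whose enzyme failed is never genotyped —
   without digestion, fragment presence is meaningless (the F2 wild-type
   fragment is the uncut amplicon itself, so only the control fragment can
   distinguish wild type from digestion failure).
2. **Biallelic loci.**  Wild-type and variant fragments above the allele
   call threshold determine the genotype; heterozygotes additionally carry
   the variant/wild-type peak-height ratio, flagged when it drops below the
   configured lower bound (mean - 2 SD of the validated ratio
   distribution) — such samples are re-tested.
3. **STR loci.**  Peaks are binned to the allele ladder.  A peak one repeat
   unit below a taller allele is stutter when at most ``stutter_max_fraction``
   of its parent; in the grey zone between that cap and
   ``str_het_ratio_min`` it is suspected contamination; above it, a genuine
   adjacent-repeat heterozygote allele.  A third allelic peak, an
   off-ladder peak, or an excessive stutter all land in ``extra_peaks``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .assay_config import (
    AssayConfig,
    StrLocusDef,
    format_allele,
    repeats_to_size,
    str_size_to_repeats,
)
from .peak_io import Peak, PeakTable

__all__ = [
    "GENOTYPES",
    "BiallelicCall",
    "StutterPeak",
    "ExtraPeak",
    "StrCall",
    "SampleReport",
    "match_peak",
    "check_digestion",
    "call_biallelic",
    "call_str",
    "call_sample",
]

GENOTYPES = ("wt/wt", "var/wt", "var/var", "no_call")

#: Short genotype labels used in report strings.
GENOTYPE_SHORT = {"wt/wt": "wt", "var/wt": "het", "var/var": "hom", "no_call": "nc"}


@dataclass(frozen=True)
class BiallelicCall:
    """Genotype call at F5 or F2 with the heterozygote height ratio."""

    locus: str
    genotype: str
    wt_height: int = 0
    var_height: int = 0
    ratio_var_over_wt: Optional[float] = None

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if (self.ratio_var_over_wt is not None) != (self.genotype == "var/wt"):
            raise ValueError("ratio defined iff genotype is var/wt")


@dataclass(frozen=True)
class StutterPeak:
    """A peak explained as PCR slippage one repeat below its parent allele."""

    size: float
    height: int
    parent_allele: str
    fraction_of_parent: float


@dataclass(frozen=True)
class ExtraPeak:
    """A peak above call threshold not explained as allele or stutter."""

    peak: Peak
    reason: str  # third_allele | stutter_excess | off_ladder
    parent_allele: Optional[str] = None
    fraction_of_parent: Optional[float] = None


@dataclass(frozen=True)
class StrCall:
    """STR genotype: 1-2 allele labels plus classified artefact peaks."""

    locus: str
    alleles: tuple[str, ...]
    allele_heights: tuple[int, ...]
    stutter_peaks: tuple[StutterPeak, ...] = ()
    extra_peaks: tuple[ExtraPeak, ...] = ()


@dataclass(frozen=True)
class SampleReport:
    """Called genotype plus QC verdict for one sample."""

    sample_id: str
    run_id: str
    f5: BiallelicCall
    f2: BiallelicCall
    strs: tuple[StrCall, ...]
    digestion_valid_mnl: bool
    digestion_valid_hind: bool
    qc_flags: frozenset[str]
    verdict: str  # PASS | RETEST | FAIL

    def str_call(self, locus: str) -> StrCall:
        for s in self.strs:
            if s.locus == locus:
                return s
        raise KeyError(f"no STR call for {locus}")

    def genotype_string(self) -> str:
        parts = [
            f"F5:{GENOTYPE_SHORT[self.f5.genotype]}",
            f"F2:{GENOTYPE_SHORT[self.f2.genotype]}",
        ]
        for s in self.strs:
            alleles = "/".join(s.alleles) if s.alleles else "nc"
            parts.append(f"{s.locus}:{alleles}")
        return " ".join(parts)


def match_peak(table: PeakTable, dye: str, size: float, tol: float) -> Optional[Peak]:
    """Highest peak within ``size +- tol`` on ``dye``, or ``None``.

    Ties on height are broken by smaller size deviation, then smaller size
    (deterministic).
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    candidates = [p for p in table.on_dye(dye) if abs(p.size - size) <= tol]
    if not candidates:
        return None
    return min(candidates, key=lambda p: (-p.height, abs(p.size - size), p.size))


def check_digestion(table: PeakTable, cfg: AssayConfig) -> tuple[bool, bool]:
    """Validate the MnlI and HindIII digests from the control fragments.

    * MnlI valid ⇔ no uncut F5 amplicon peak (289 bp) at or above the call
      threshold.
    * HindIII valid ⇔ no uncut control peak (339 bp) AND the cut control
      product (276 bp) is present at or above the call threshold.
    """
    thr = cfg.thresholds
    uncut_f5 = cfg.rule("F5", "uncut")
    p = match_peak(table, uncut_f5.dye, uncut_f5.apparent_size, thr.size_match_tol)
    mnl_valid = p is None or p.height < thr.allele_call_rfu

    uncut_ctrl = cfg.rule("FGA_intron1", "control_uncut")
    cut_ctrl = cfg.rule("FGA_intron1", "control_cut")
    p_uncut = match_peak(table, uncut_ctrl.dye, uncut_ctrl.apparent_size, thr.size_match_tol)
    p_cut = match_peak(table, cut_ctrl.dye, cut_ctrl.apparent_size, thr.size_match_tol)
    hind_valid = (p_uncut is None or p_uncut.height < thr.allele_call_rfu) and (
        p_cut is not None and p_cut.height >= thr.allele_call_rfu
    )
    return mnl_valid, hind_valid


def call_biallelic(
    table: PeakTable, locus: str, cfg: AssayConfig
) -> tuple[BiallelicCall, set[str]]:
    """Call F5 or F2 from its wild-type/variant fragment peaks.

    Callers must gate on :func:`check_digestion` — this function assumes the
    locus's digest was valid.  Returns the call plus QC flags
    (``RATIO_LOW_*`` when a heterozygote's variant/wt height ratio falls
    below the configured lower bound; ``LOW_SIGNAL`` when neither fragment
    reaches the call threshold).
    """
    thr = cfg.thresholds
    wt_rule = cfg.rule(locus, "wt")
    var_rule = cfg.rule(locus, "variant")
    p_wt = match_peak(table, wt_rule.dye, wt_rule.apparent_size, thr.size_match_tol)
    p_var = match_peak(table, var_rule.dye, var_rule.apparent_size, thr.size_match_tol)
    wt_h = p_wt.height if p_wt is not None and p_wt.height >= thr.allele_call_rfu else 0
    var_h = p_var.height if p_var is not None and p_var.height >= thr.allele_call_rfu else 0

    flags: set[str] = set()
    if wt_h and var_h:
        ratio = var_h / wt_h
        call = BiallelicCall(locus, "var/wt", wt_h, var_h, ratio)
        ratio_min = thr.het_ratio_min_f5 if locus == "F5" else thr.het_ratio_min_f2
        if ratio < ratio_min:
            flags.add(f"RATIO_LOW_{locus}")
    elif wt_h:
        call = BiallelicCall(locus, "wt/wt", wt_h, 0)
    elif var_h:
        call = BiallelicCall(locus, "var/var", 0, var_h)
    else:
        call = BiallelicCall(locus, "no_call")
        flags.add("LOW_SIGNAL")
    return call, flags


def call_str(
    table: PeakTable, locus: StrLocusDef, cfg: AssayConfig
) -> tuple[StrCall, set[str]]:
    """Call one STR locus: bin peaks to the ladder, classify stutter.

    Candidate peaks (>= call threshold on the locus dye) are processed in
    descending height order.  Each is first tested as stutter of an
    already-accepted taller allele (exactly one repeat unit shorter):

    * fraction <= ``stutter_max_fraction``  -> stutter;
    * fraction in (cap, ``str_het_ratio_min``) -> suspected contamination
      (``stutter_excess`` extra peak);
    * fraction >= ``str_het_ratio_min``     -> treated as a real allele.

    Unexplained peaks beyond the two-allele diploid expectation, peaks that
    do not bin to the ladder, and second-allele candidates far below the
    plausible heterozygote balance (< ``str_het_ratio_min`` of the tallest
    allele) are reported as extra peaks.
    """
    thr = cfg.thresholds
    candidates = [
        p for p in table.on_dye(locus.dye) if p.height >= thr.allele_call_rfu
    ]
    candidates.sort(key=lambda p: (-p.height, p.size))

    alleles: list[tuple[float, Peak]] = []  # (repeats, peak)
    stutters: list[StutterPeak] = []
    extras: list[ExtraPeak] = []
    flags: set[str] = set()

    for peak in candidates:
        r = str_size_to_repeats(locus, peak.size, tol=thr.str_bin_tol, extend_below=1)
        if r is None:
            extras.append(ExtraPeak(peak, "off_ladder"))
            flags.add("OFF_LADDER")
            continue
        # stutter test against taller accepted alleles one full repeat above
        parent = next(
            (
                (pr, pp)
                for pr, pp in alleles
                if abs(repeats_to_size(locus, pr) - peak.size - locus.repeat_unit) <= thr.str_bin_tol
            ),
            None,
        )
        if parent is not None:
            pr, pp = parent
            fraction = peak.height / pp.height
            if fraction <= thr.stutter_max_fraction:
                stutters.append(
                    StutterPeak(peak.size, peak.height, format_allele(pr), fraction)
                )
                continue
            if fraction < thr.str_het_ratio_min:
                extras.append(
                    ExtraPeak(peak, "stutter_excess", format_allele(pr), fraction)
                )
                flags.add("STUTTER_EXCESS")
                continue
            # tall enough to be a genuine adjacent-repeat sister allele
        if r < locus.min_repeats - 1e-9:
            # only reachable as stutter of the smallest ladder allele
            extras.append(ExtraPeak(peak, "off_ladder"))
            flags.add("OFF_LADDER")
        elif len(alleles) >= 2:
            extras.append(ExtraPeak(peak, "third_allele"))
            flags.add("EXTRA_STR_ALLELE")
        elif alleles and peak.height < thr.str_het_ratio_min * alleles[0][1].height:
            # far too small to be the sister allele of a heterozygote
            extras.append(ExtraPeak(peak, "imbalanced"))
            flags.add("EXTRA_STR_ALLELE")
        else:
            alleles.append((r, peak))

    if not alleles:
        flags.add("LOW_SIGNAL")
    alleles.sort(key=lambda a: a[0])
    call = StrCall(
        locus=locus.locus_id,
        alleles=tuple(format_allele(r) for r, _ in alleles),
        allele_heights=tuple(p.height for _, p in alleles),
        stutter_peaks=tuple(stutters),
        extra_peaks=tuple(extras),
    )
    return call, flags


def call_sample(table: PeakTable, cfg: AssayConfig) -> SampleReport:
    """Full per-sample interpretation: digestion gates, both loci, both STRs.

    Verdict: ``FAIL`` on any digestion failure; ``RETEST`` on any other QC
    flag (ratio imbalance, extra/off-ladder STR peaks, stutter excess, low
    signal); ``PASS`` only with an empty flag set.
    """
    thr = cfg.thresholds
    mnl_valid, hind_valid = check_digestion(table, cfg)
    flags: set[str] = set()

    if mnl_valid:
        f5, f5_flags = call_biallelic(table, "F5", cfg)
        flags |= f5_flags
    else:
        f5 = BiallelicCall("F5", "no_call")
        flags.add("UNDIGESTED_MNL")

    if hind_valid:
        f2, f2_flags = call_biallelic(table, "F2", cfg)
        flags |= f2_flags
    else:
        f2 = BiallelicCall("F2", "no_call")
        flags.add("UNDIGESTED_HIND")

    strs = []
    for locus in cfg.str_loci:
        # the FGA STR is itself an MnlI digestion product; skip when invalid
        if locus.uncut_size_shift and not mnl_valid:
            strs.append(StrCall(locus.locus_id, (), ()))
            continue
        s, s_flags = call_str(table, locus, cfg)
        strs.append(s)
        flags |= s_flags

    if "UNDIGESTED_MNL" in flags or "UNDIGESTED_HIND" in flags:
        verdict = "FAIL"
    elif flags:
        verdict = "RETEST"
    else:
        verdict = "PASS"

    return SampleReport(
        sample_id=table.sample_id,
        run_id=table.run_id,
        f5=f5,
        f2=f2,
        strs=tuple(strs),
        digestion_valid_mnl=mnl_valid,
        digestion_valid_hind=hind_valid,
        qc_flags=frozenset(flags),
        verdict=verdict,
    )
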