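"""Cross-sample QC: contamination criteria, identity matching, random-match probability.

Three criteria flag a sample as containing foreign DNA, mirroring how the
dual-STR design is read out in practice:

* **EXTRA_ALLELE** — an unexplained peak at an STR locus (a third allelic
  peak, or an off-ladder peak), or an unexpected extra allele pattern at a
  biallelic locus;
* **STUTTER_EXCESS** — a peak at a stutter position whose height fraction
  exceeds the configured cap (stutter mean + 2 SD): a contaminant allele
  hiding under a stutter still adds height;
* **RATIO_IMBALANCE** — a heterozygous F5/F2 peak-height ratio below its
  validated lower bound.  This is delegated to the caller's ratio flags
  rather than recomputed: a low ratio triggers a re-test even without an
  additional STR peak.

The design has a documented blind spot: a contaminant sharing all four STR
alleles (or their stutter positions, below the excess cap) with the host
sample is undetectable by construction.

Identity matching compares the STR allele multisets of two reports (e.g.
inter-operator repeat testing); the random-match probability quantifies how
discriminating that comparison is under Hardy-Weinberg equilibrium.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .assay_config import AssayConfig, parse_allele
from .caller import SampleReport

__all__ = [
    "CRITERIA",
    "ContaminationVerdict",
    "IdentityComparison",
    "FreqTable",
    "assess_contamination",
    "criteria_from_flags",
    "compare_identity",
    "random_match_probability",
    "demo_frequency_table",
]

CRITERIA = ("EXTRA_ALLELE", "STUTTER_EXCESS", "RATIO_IMBALANCE")

#: Caller QC flag -> contamination criterion (for flag-level report rows).
FLAG_TO_CRITERION = {
    "EXTRA_STR_ALLELE": "EXTRA_ALLELE",
    "OFF_LADDER": "EXTRA_ALLELE",
    "STUTTER_EXCESS": "STUTTER_EXCESS",
    "RATIO_LOW_F5": "RATIO_IMBALANCE",
    "RATIO_LOW_F2": "RATIO_IMBALANCE",
}


def criteria_from_flags(flags) -> frozenset:
    """Map caller QC flags onto the three contamination criteria."""
    return frozenset(FLAG_TO_CRITERION[f] for f in flags if f in FLAG_TO_CRITERION)


@dataclass(frozen=True)
class ContaminationVerdict:
    """Outcome of the three-criterion contamination screen for one sample."""

    sample_id: str
    detected: bool
    criteria_hit: frozenset[str]
    evidence: tuple[tuple[str, str, str], ...]  # (locus, peak description, explanation)

    def __post_init__(self) -> None:
        if self.detected != bool(self.criteria_hit):
            raise ValueError("detected must equal criteria_hit non-empty")


@dataclass(frozen=True)
class IdentityComparison:
    """STR-profile comparison of two reports (sample mix-up screen)."""

    sample_a: str
    sample_b: str
    shared_loci: tuple[str, ...]
    excluded_loci: tuple[str, ...]
    status: str  # match | mismatch | incomparable

    @property
    def match(self) -> Optional[bool]:
        if self.status == "incomparable":
            return None
        return self.status == "match"


def assess_contamination(report: SampleReport, cfg: AssayConfig) -> ContaminationVerdict:
    """Apply the three contamination criteria to a called sample."""
    hit: set[str] = set()
    evidence: list[tuple[str, str, str]] = []

    for s in report.strs:
        for extra in s.extra_peaks:
            if extra.reason == "stutter_excess":
                hit.add("STUTTER_EXCESS")
                evidence.append(
                    (
                        s.locus,
                        f"{extra.peak.size:.1f} bp / {extra.peak.height} RFU",
                        f"stutter position of allele {extra.parent_allele} at "
                        f"{100 * (extra.fraction_of_parent or 0):.1f}% of parent",
                    )
                )
            else:
                hit.add("EXTRA_ALLELE")
                evidence.append(
                    (
                        s.locus,
                        f"{extra.peak.size:.1f} bp / {extra.peak.height} RFU",
                        extra.reason,
                    )
                )

    for flag, locus in (("RATIO_LOW_F5", "F5"), ("RATIO_LOW_F2", "F2")):
        if flag in report.qc_flags:
            call = report.f5 if locus == "F5" else report.f2
            hit.add("RATIO_IMBALANCE")
            evidence.append(
                (
                    locus,
                    f"var {call.var_height} / wt {call.wt_height} RFU",
                    f"het ratio {call.ratio_var_over_wt:.2f} below lower bound",
                )
            )

    return ContaminationVerdict(
        sample_id=report.sample_id,
        detected=bool(hit),
        criteria_hit=frozenset(hit),
        evidence=tuple(evidence),
    )


def compare_identity(a: SampleReport, b: SampleReport) -> IdentityComparison:
    """Compare the STR profiles of two reports.

    Match requires identical allele multisets at every locus called in both
    reports (a single observed allele is read as a homozygote).  Loci
    uncalled in either report are excluded; if no locus is co-called the
    comparison is *incomparable* — distinct from a mismatch.
    """
    shared, excluded = [], []
    all_equal = True
    loci = [s.locus for s in a.strs]
    for locus in loci:
        try:
            ca, cb = a.str_call(locus), b.str_call(locus)
        except KeyError:
            excluded.append(locus)
            continue
        if not ca.alleles or not cb.alleles:
            excluded.append(locus)
            continue
        shared.append(locus)

        def multiset(alleles: tuple[str, ...]) -> tuple[str, ...]:
            return tuple(sorted(alleles)) if len(alleles) == 2 else (alleles[0], alleles[0])

        if multiset(ca.alleles) != multiset(cb.alleles):
            all_equal = False
    if not shared:
        status = "incomparable"
    else:
        status = "match" if all_equal else "mismatch"
    return IdentityComparison(
        sample_a=a.sample_id,
        sample_b=b.sample_id,
        shared_loci=tuple(shared),
        excluded_loci=tuple(excluded),
        status=status,
    )


@dataclass(frozen=True)
class FreqTable:
    """Per-locus STR allele population frequencies.

    Partial tables are allowed; ``min_freq`` is the documented floor applied
    to alleles absent from the table (set ``min_freq=None`` to make missing
    alleles an error).
    """

    loci: dict[str, dict[str, float]]
    min_freq: Optional[float] = 0.001

    def __post_init__(self) -> None:
        for locus, freqs in self.loci.items():
            if not freqs:
                raise ValueError(f"{locus}: empty frequency table")
            for allele, f in freqs.items():
                if not 0 < f <= 1:
                    raise ValueError(f"{locus} allele {allele}: frequency {f} not in (0, 1]")
            total = sum(freqs.values())
            if total > 1 + 1e-6:
                raise ValueError(f"{locus}: frequencies sum to {total:.4f} > 1")

    def frequency(self, locus: str, allele: Union[str, float]) -> float:
        label = _canonical_label(allele)
        freqs = self.loci[locus]
        if label in freqs:
            return freqs[label]
        if self.min_freq is None:
            raise KeyError(f"allele {label} absent from {locus} table and no floor set")
        return self.min_freq

    @classmethod
    def from_csv(cls, path: Union[str, Path], min_freq: Optional[float] = 0.001) -> "FreqTable":
        frame = pd.read_csv(path, dtype={"locus": str, "allele": str})
        missing = {"locus", "allele", "frequency"} - set(frame.columns)
        if missing:
            raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
        loci: dict[str, dict[str, float]] = {}
        for row in frame.itertuples(index=False):
            loci.setdefault(row.locus, {})[_canonical_label(row.allele)] = float(row.frequency)
        return cls(loci=loci, min_freq=min_freq)


def _canonical_label(allele: Union[str, float]) -> str:
    r = parse_allele(allele)
    n = int(r)
    p = int(round((r - n) * 10))
    return f"{n}.{p}" if p else str(n)


def demo_frequency_table() -> FreqTable:
    """The packaged demo frequency table (synthetic fixture).

    Allele frequencies are synthetic, shaped like forensic population tables
    for FGA and SE33 (FGA moderately, SE33 highly polymorphic); they are
    illustrative, not a published population survey.
    """
    with resources.as_file(
        resources.files("rflpmux.data").joinpath("synthetic_str_frequencies_demo.csv")
    ) as p:
        return FreqTable.from_csv(p)


def random_match_probability(
    genotype: dict[str, tuple[Union[str, float], Union[str, float]]],
    freqs: FreqTable,
) -> float:
    """Hardy-Weinberg random-match probability of a multi-locus STR genotype.

    Product over loci of p^2 for homozygotes and 2pq for heterozygotes.
    Multiplying in an extra locus can only decrease the value.
    """
    rmp = 1.0
    for locus, (a1, a2) in genotype.items():
        p = freqs.frequency(locus, a1)
        if _canonical_label(a1) == _canonical_label(a2):
            rmp *= p * p
        else:
            q = freqs.frequency(locus, a2)
            rmp *= 2 * p * q
    return rmp
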