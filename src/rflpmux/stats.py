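"""Validation statistics: threshold derivation and proportion CIs.

The assay's interpretation thresholds are derived from bench-validated
moments (mean ± k·SD): the heterozygote ratio lower bound is mean − 2 SD,
the stutter cap is mean + 2 SD, and the allele-call threshold is 3× the
noise ceiling.  Concordance, sensitivity and specificity of validation
cohorts are summarised with Wilson score confidence intervals (Wilson —
not Clopper-Pearson — matches the printed interval at 30/30).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import math

import pandas as pd

__all__ = [
    "Z_95",
    "ProportionCI",
    "threshold_from_moments",
    "wilson_ci",
    "concordance_summary",
]

#: Two-sided 95% normal quantile, fixed.
Z_95 = 1.959964


@dataclass(frozen=True)
class ProportionCI:
    """A binomial proportion with its Wilson score interval."""

    successes: int
    trials: int
    point: float
    lower: float
    upper: float
    method: str = "wilson"

    def __post_init__(self) -> None:
        if not 0 <= self.lower <= self.point <= self.upper <= 1:
            raise ValueError("interval must satisfy 0 <= lower <= point <= upper <= 1")

    def __str__(self) -> str:
        return f"{self.point:.2f} [{self.lower:.2f}-{self.upper:.2f}]"


def threshold_from_moments(
    mean: float, sd: float, k: float, rounding: str = "none"
) -> float:
    """Derive a threshold as ``mean + k*sd`` with a printing-convention rounding.

    ``rounding``: ``"none"`` (raw), ``"two_decimals"`` (ratio thresholds),
    ``"integer"`` (percent thresholds).
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    value = mean + k * sd
    if rounding == "two_decimals":
        return round(value, 2)
    if rounding == "integer":
        return float(round(value))
    if rounding != "none":
        raise ValueError(f"unknown rounding policy {rounding!r}")
    return value


def wilson_ci(successes: int, trials: int, confidence: float = 0.95) -> ProportionCI:
    """Wilson score confidence interval for a binomial proportion.

    The 95% quantile is fixed at ``Z_95`` so printed bounds are stable to
    their last digit; at ``successes == trials`` the lower bound has the
    closed form ``n / (n + z^2)``.
    """
    if trials < 1 or not 0 <= successes <= trials:
        raise ValueError(f"invalid counts {successes}/{trials}")
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    if confidence == 0.95:
        z = Z_95
    else:
        from scipy.stats import norm

        z = float(norm.ppf(0.5 + confidence / 2))
    p = successes / trials
    n = trials
    denom = 1 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    return ProportionCI(
        successes=successes,
        trials=trials,
        point=p,
        lower=min(max(centre - half, 0.0), p),
        upper=max(min(centre + half, 1.0), p),
    )


def concordance_summary(truth: Sequence, called: Sequence) -> pd.DataFrame:
    """Tabulate genotype concordance of called reports against truth.

    ``truth`` holds :class:`~rflpmux.simulator.SampleGenotype`-like objects
    (``f5``/``f2`` states), ``called`` the matching
    :class:`~rflpmux.caller.SampleReport` list in the same order.  A sample
    is concordant when the called F5 **and** F2 genotypes both match truth;
    carriers are samples whose true genotype holds a variant allele at
    either locus.  Returns one row per observed genotype category, an
    overall row, and sensitivity/specificity rows (concordant carriers /
    all carriers, concordant non-carriers / all non-carriers), all with
    Wilson 95% CIs.  Empty categories are simply absent; an empty carrier
    or non-carrier stratum yields no sensitivity/specificity row.
    """
    if len(truth) != len(called):
        raise ValueError(f"length mismatch: {len(truth)} truths vs {len(called)} reports")

    per_cat: dict[tuple[str, str], list[int]] = {}
    carriers = [0, 0]      # concordant, total
    non_carriers = [0, 0]
    for t, r in zip(truth, called):
        ok = r.f5.genotype == t.f5 and r.f2.genotype == t.f2
        key = (t.f5, t.f2)
        per_cat.setdefault(key, [0, 0])
        per_cat[key][0] += int(ok)
        per_cat[key][1] += 1
        bucket = carriers if (t.f5 != "wt/wt" or t.f2 != "wt/wt") else non_carriers
        bucket[0] += int(ok)
        bucket[1] += 1

    rows = []

    def row(label: str, hits: int, n: int) -> dict:
        ci = wilson_ci(hits, n)
        return {
            "category": label,
            "concordant": hits,
            "n": n,
            "fraction": hits / n,
            "ci_lower": ci.lower,
            "ci_upper": ci.upper,
        }

    for (f5, f2), (hits, n) in sorted(per_cat.items()):
        rows.append(row(f"F5 {f5} / F2 {f2}", hits, n))
    total_hits = sum(h for h, _ in per_cat.values())
    total_n = sum(n for _, n in per_cat.values())
    rows.append(row("overall", total_hits, total_n))
    if carriers[1]:
        rows.append(row("sensitivity (carriers)", carriers[0], carriers[1]))
    if non_carriers[1]:
        rows.append(row("specificity (non-carriers)", non_carriers[0], non_carriers[1]))
    return pd.DataFrame(rows)
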