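"""Synthetic peak-table generator reproducing the assay's statistical structure.

The generator emits per-sample peak tables with the same statistical
behaviour the assay shows on the bench, so every validation experiment can
be replayed in silico:

* per-allele peak heights log-normal around a configurable median, clipped
  at the 32,000 RFU saturation ceiling;
* heterozygous variant/wild-type height ratios drawn from N(0.61, 0.06^2)
  for F5 and N(0.67, 0.09^2) for F2 (the validated bench distributions);
* STR stutter one repeat unit below each allele at N(7.6%, 1.8^2%) of the
  parent height for FGA and N(7.6%, 1.6^2%) for SE33;
* fluorescence background noise peaks strictly below 50 RFU;
* digestion-failure modes that resurrect the uncut 289/339 bp amplicons
  (and shift the FGA STR, itself an MnlI product, by +56 bp);
* two-person mixtures with contaminant peak heights scaled linearly by the
  ng:ng mixing ratio.

Everything is driven by one :class:`numpy.random.Generator`, so a fixed
seed reproduces a peak table byte-exactly through ``write_peak_tables``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np

from .assay_config import AssayConfig, StrLocusDef, default_config, format_allele, repeats_to_size
from .caller import call_sample
from .contamination import FreqTable, assess_contamination, demo_frequency_table
from .peak_io import Peak, PeakTable

__all__ = [
    "SimParams",
    "SampleGenotype",
    "MixtureSpec",
    "CONCORDANCE_COMPOSITION",
    "MIXTURE_POOL",
    "sample_genotype",
    "synthesize",
    "concordance_study",
    "mixture_study",
    "ratio_stats",
    "stutter_stats",
    "run_validation_study",
]


@dataclass(frozen=True)
class SimParams:
    """Tunable distributions of the generator (bench-validated defaults).

    ``het_ratio_*`` are (mean, sd) of the variant/wild-type height ratio in
    heterozygotes; ``stutter_fraction_*`` are (mean, sd) of stutter/parent
    height fractions.  ``base_height_median``/``sigma`` parameterise the
    log-normal per-locus peak height; ``allele_imbalance_sigma`` is the
    log-scale sd between sister STR alleles.  Noise peaks are Poisson in
    number with heights uniform below the noise ceiling.
    """

    het_ratio_f5: tuple[float, float] = (0.61, 0.06)
    het_ratio_f2: tuple[float, float] = (0.67, 0.09)
    stutter_fraction_fga: tuple[float, float] = (0.076, 0.018)
    stutter_fraction_se33: tuple[float, float] = (0.076, 0.016)
    base_height_median: float = 8000.0
    base_height_sigma: float = 0.30
    allele_imbalance_sigma: float = 0.10
    noise_peak_mean: float = 3.0
    noise_height_max: float = 50.0
    saturation: float = 32000.0
    f5_variant_freq: float = 0.025
    f2_variant_freq: float = 0.011

    def __post_init__(self) -> None:
        for name in ("het_ratio_f5", "het_ratio_f2",
                     "stutter_fraction_fga", "stutter_fraction_se33"):
            mean, sd = getattr(self, name)
            if not 0 < mean < 1:
                raise ValueError(f"{name}: mean must be in (0, 1)")
            if sd < 0:
                raise ValueError(f"{name}: sd must be >= 0")

    def stutter_params(self, locus_id: str) -> tuple[float, float]:
        return self.stutter_fraction_fga if locus_id == "FGA" else self.stutter_fraction_se33


@dataclass(frozen=True)
class SampleGenotype:
    """Ground-truth genotype: F5 and F2 states plus the two STR genotypes."""

    f5: str = "wt/wt"
    f2: str = "wt/wt"
    fga: tuple[float, float] = (21.0, 24.0)
    se33: tuple[float, float] = (17.0, 28.2)

    def __post_init__(self) -> None:
        for name in ("f5", "f2"):
            if getattr(self, name) not in ("wt/wt", "var/wt", "var/var"):
                raise ValueError(f"{name}: invalid state {getattr(self, name)!r}")
        object.__setattr__(self, "fga", tuple(sorted(self.fga)))
        object.__setattr__(self, "se33", tuple(sorted(self.se33)))

    def str_alleles(self, locus_id: str) -> tuple[float, float]:
        return self.fga if locus_id == "FGA" else self.se33

    def str_profile(self) -> tuple[tuple[float, ...], tuple[float, ...]]:
        return (self.fga, self.se33)

    def is_carrier(self) -> bool:
        return self.f5 != "wt/wt" or self.f2 != "wt/wt"


@dataclass(frozen=True)
class MixtureSpec:
    """Instruction for one synthetic sample.

    ``ratio`` is contaminant:primary in ng:ng (e.g. 0.05 for a 1:20
    mixture).  ``digestion_failure`` in {none, mnl, hind, both}.
    """

    primary: SampleGenotype
    contaminant: Optional[SampleGenotype] = None
    ratio: float = 0.0
    digestion_failure: str = "none"

    def __post_init__(self) -> None:
        if self.contaminant is not None and self.ratio <= 0:
            raise ValueError("ratio must be > 0 when a contaminant is present")
        if self.digestion_failure not in ("none", "mnl", "hind", "both"):
            raise ValueError(f"invalid digestion_failure {self.digestion_failure!r}")


def _draw_state(freq: float, rng: np.random.Generator) -> str:
    """Hardy-Weinberg genotype state from a variant allele frequency."""
    u = rng.random()
    if u < freq * freq:
        return "var/var"
    if u < freq * freq + 2 * freq * (1 - freq):
        return "var/wt"
    return "wt/wt"


def sample_genotype(
    freqs: FreqTable,
    rng: np.random.Generator,
    variant_states: Optional[tuple[str, str]] = None,
    params: Optional[SimParams] = None,
) -> SampleGenotype:
    """Draw a genotype: STR alleles i.i.d. under Hardy-Weinberg from ``freqs``,
    F5/F2 states fixed by ``variant_states`` or drawn from the configured
    carrier allele frequencies."""
    params = params or SimParams()

    def draw_pair(locus: str) -> tuple[float, float]:
        table = freqs.loci[locus]
        labels = sorted(table, key=float)
        probs = np.array([table[a] for a in labels], dtype=float)
        probs = probs / probs.sum()
        picks = rng.choice(len(labels), size=2, p=probs)
        return tuple(sorted(float(labels[i]) for i in picks))

    fga = draw_pair("FGA")
    se33 = draw_pair("SE33")
    if variant_states is not None:
        f5, f2 = variant_states
    else:
        f5 = _draw_state(params.f5_variant_freq, rng)
        f2 = _draw_state(params.f2_variant_freq, rng)
    return SampleGenotype(f5=f5, f2=f2, fga=fga, se33=se33)


def _lognormal(median: float, sigma: float, rng: np.random.Generator) -> float:
    return float(median * math.exp(sigma * rng.standard_normal()))


def _het_ratio(mean_sd: tuple[float, float], rng: np.random.Generator) -> float:
    mean, sd = mean_sd
    # truncated to (0, 1.5); the defaults put the bounds far in the tails
    return float(min(max(mean + sd * rng.standard_normal(), 1e-6), 1.5))


def synthesize(
    spec: MixtureSpec,
    params: SimParams,
    cfg: AssayConfig,
    rng: np.random.Generator,
    sample_id: str = "S1",
    run_id: str = "R1",
) -> PeakTable:
    """Generate the peak table of one (possibly mixed) sample.

    Contaminant peaks are built with the same machinery and scaled linearly
    by the mixing ratio; coincident sizes are summed and then clipped at
    the saturation ceiling.
    """
    fail_mnl = spec.digestion_failure in ("mnl", "both")
    fail_hind = spec.digestion_failure in ("hind", "both")
    acc: dict[tuple[str, float], float] = {}

    def add(dye: str, size: float, height: float) -> None:
        if height < 1.0:
            return
        key = (dye, round(size, 1))
        acc[key] = acc.get(key, 0.0) + height

    sources: list[tuple[SampleGenotype, float]] = [(spec.primary, 1.0)]
    if spec.contaminant is not None:
        sources.append((spec.contaminant, spec.ratio))

    f5_wt = cfg.rule("F5", "wt")
    f5_var = cfg.rule("F5", "variant")
    f5_uncut = cfg.rule("F5", "uncut")
    f2_wt = cfg.rule("F2", "wt")
    f2_var = cfg.rule("F2", "variant")
    ctrl_cut = cfg.rule("FGA_intron1", "control_cut")
    ctrl_uncut = cfg.rule("FGA_intron1", "control_uncut")

    for genotype, scale in sources:
        # --- F5 (MnlI digest) ---------------------------------------------
        h5 = _lognormal(params.base_height_median, params.base_height_sigma, rng) * scale
        if genotype.f5 == "var/wt":
            r5 = _het_ratio(params.het_ratio_f5, rng)
        if fail_mnl:
            total = h5 * (1 + r5) if genotype.f5 == "var/wt" else h5
            add(f5_uncut.dye, f5_uncut.apparent_size, total)
        elif genotype.f5 == "wt/wt":
            add(f5_wt.dye, f5_wt.apparent_size, h5)
        elif genotype.f5 == "var/wt":
            add(f5_wt.dye, f5_wt.apparent_size, h5)
            add(f5_var.dye, f5_var.apparent_size, h5 * r5)
        else:
            add(f5_var.dye, f5_var.apparent_size, h5)

        # --- F2 (HindIII digest; wild type is the uncut amplicon) ----------
        h2 = _lognormal(params.base_height_median, params.base_height_sigma, rng) * scale
        if genotype.f2 == "var/wt":
            r2 = _het_ratio(params.het_ratio_f2, rng)
        if fail_hind:
            total = h2 * (1 + r2) if genotype.f2 == "var/wt" else h2
            add(f2_wt.dye, f2_wt.apparent_size, total)
        elif genotype.f2 == "wt/wt":
            add(f2_wt.dye, f2_wt.apparent_size, h2)
        elif genotype.f2 == "var/wt":
            add(f2_wt.dye, f2_wt.apparent_size, h2)
            add(f2_var.dye, f2_var.apparent_size, h2 * r2)
        else:
            add(f2_var.dye, f2_var.apparent_size, h2)

        # --- HindIII digestion control --------------------------------------
        hc = _lognormal(params.base_height_median, params.base_height_sigma, rng) * scale
        if fail_hind:
            add(ctrl_uncut.dye, ctrl_uncut.apparent_size, hc)
        else:
            add(ctrl_cut.dye, ctrl_cut.apparent_size, hc)

        # --- STR loci --------------------------------------------------------
        for locus in cfg.str_loci:
            shift = locus.uncut_size_shift if fail_mnl else 0.0
            h_locus = _lognormal(params.base_height_median, params.base_height_sigma, rng) * scale
            st_mean, st_sd = params.stutter_params(locus.locus_id)
            for allele in genotype.str_alleles(locus.locus_id):
                h_allele = h_locus * math.exp(
                    params.allele_imbalance_sigma * rng.standard_normal()
                )
                size = repeats_to_size(locus, allele) + shift
                add(locus.dye, size, h_allele)
                frac = max(st_mean + st_sd * rng.standard_normal(), 0.0)
                add(locus.dye, size - locus.repeat_unit, frac * h_allele)

    # --- background fluorescence noise (always below the noise ceiling) ----
    n_noise = int(rng.poisson(params.noise_peak_mean))
    dyes = ("blue", "green", "black", "red", "orange")
    for _ in range(n_noise):
        dye = dyes[int(rng.integers(len(dyes)))]
        size = round(float(rng.uniform(60.0, 450.0)), 1)
        height = 1 + int(rng.uniform(0.0, params.noise_height_max - 1.0))
        add(dye, size, float(height))

    peaks = []
    for (dye, size), height in acc.items():
        saturated = height > params.saturation
        h = int(round(min(height, params.saturation)))
        if h >= 1:
            peaks.append(Peak(dye=dye, size=size, height=h, saturated=saturated))
    return PeakTable(sample_id=sample_id, run_id=run_id, peaks=peaks)


# ---------------------------------------------------------------------------
# validation-study replicas
# ---------------------------------------------------------------------------

#: Genotype composition of the accuracy cohort: (F5 state, F2 state, n).
CONCORDANCE_COMPOSITION: tuple[tuple[str, str, int], ...] = (
    ("wt/wt", "wt/wt", 31),
    ("var/wt", "wt/wt", 16),
    ("wt/wt", "var/wt", 14),
    ("var/var", "wt/wt", 1),
)

#: Donor pool of the mixture study: (F5 state, F2 state, n).
MIXTURE_POOL: tuple[tuple[str, str, int], ...] = (
    ("wt/wt", "wt/wt", 14),
    ("var/wt", "wt/wt", 5),
    ("wt/wt", "var/wt", 3),
)


def _pool_states(pool: Sequence[tuple[str, str, int]], rng: np.random.Generator) -> tuple[str, str]:
    weights = np.array([n for _, _, n in pool], dtype=float)
    i = int(rng.choice(len(pool), p=weights / weights.sum()))
    return pool[i][0], pool[i][1]


def concordance_study(
    rng: np.random.Generator,
    params: Optional[SimParams] = None,
    cfg: Optional[AssayConfig] = None,
    freqs: Optional[FreqTable] = None,
    composition: Sequence[tuple[str, str, int]] = CONCORDANCE_COMPOSITION,
) -> dict:
    """Simulate the accuracy cohort, call every sample, tabulate agreement.

    Returns per-category and overall concordance of the called F5/F2
    genotypes against simulated truth.
    """
    params = params or SimParams()
    cfg = cfg or default_config()
    freqs = freqs or demo_frequency_table()
    categories = []
    total = concordant_total = 0
    truths, reports = [], []
    for f5, f2, n in composition:
        hits = 0
        for i in range(n):
            truth = sample_genotype(freqs, rng, variant_states=(f5, f2), params=params)
            table = synthesize(
                MixtureSpec(primary=truth), params, cfg, rng,
                sample_id=f"C{len(truths) + 1:03d}",
            )
            report = call_sample(table, cfg)
            truths.append(truth)
            reports.append(report)
            if report.f5.genotype == f5 and report.f2.genotype == f2:
                hits += 1
        categories.append({"f5": f5, "f2": f2, "n": n, "concordant": hits})
        total += n
        concordant_total += hits
    return {
        "categories": categories,
        "n": total,
        "concordant": concordant_total,
        "percent": 100.0 * concordant_total / total,
        "truths": truths,
        "reports": reports,
    }


def mixture_study(
    ratio: float,
    rng: np.random.Generator,
    n: int = 30,
    params: Optional[SimParams] = None,
    cfg: Optional[AssayConfig] = None,
    freqs: Optional[FreqTable] = None,
    pool: Sequence[tuple[str, str, int]] = MIXTURE_POOL,
) -> dict:
    """Simulate ``n`` two-person mixtures at the given ng:ng ratio and screen
    them with the three contamination criteria.

    Primary and contaminant are distinct individuals (contaminant redrawn on
    a full STR-profile collision), with F5/F2 states drawn from the donor
    pool's proportions, as in the bench mixture study.
    """
    params = params or SimParams()
    cfg = cfg or default_config()
    freqs = freqs or demo_frequency_table()
    detected = 0
    per_criterion = {c: 0 for c in ("EXTRA_ALLELE", "STUTTER_EXCESS", "RATIO_IMBALANCE")}
    verdicts = []
    for i in range(n):
        primary = sample_genotype(freqs, rng, variant_states=_pool_states(pool, rng), params=params)
        while True:
            contaminant = sample_genotype(
                freqs, rng, variant_states=_pool_states(pool, rng), params=params
            )
            if contaminant.str_profile() != primary.str_profile():
                break
        table = synthesize(
            MixtureSpec(primary=primary, contaminant=contaminant, ratio=ratio),
            params, cfg, rng, sample_id=f"M{i + 1:03d}",
        )
        verdict = assess_contamination(call_sample(table, cfg), cfg)
        verdicts.append(verdict)
        if verdict.detected:
            detected += 1
        for c in verdict.criteria_hit:
            per_criterion[c] += 1
    return {
        "ratio": ratio,
        "n": n,
        "detected": detected,
        "percent": 100.0 * detected / n,
        "per_criterion": per_criterion,
        "verdicts": verdicts,
    }


def ratio_stats(
    locus: str,
    rng: np.random.Generator,
    n: int = 1000,
    params: Optional[SimParams] = None,
    cfg: Optional[AssayConfig] = None,
    freqs: Optional[FreqTable] = None,
) -> dict:
    """Empirical mean +- sd of the called het variant/wt height ratio over
    ``n`` simulated heterozygotes at F5 or F2 (generator parameter recovery)."""
    params = params or SimParams()
    cfg = cfg or default_config()
    freqs = freqs or demo_frequency_table()
    states = ("var/wt", "wt/wt") if locus == "F5" else ("wt/wt", "var/wt")
    ratios = []
    for i in range(n):
        truth = sample_genotype(freqs, rng, variant_states=states, params=params)
        table = synthesize(MixtureSpec(primary=truth), params, cfg, rng, sample_id=f"R{i}")
        report = call_sample(table, cfg)
        call = report.f5 if locus == "F5" else report.f2
        if call.ratio_var_over_wt is not None:
            ratios.append(call.ratio_var_over_wt)
    arr = np.asarray(ratios)
    return {"locus": locus, "n": len(arr), "mean": float(arr.mean()), "sd": float(arr.std(ddof=1))}


def stutter_stats(
    locus: str,
    rng: np.random.Generator,
    n: int = 1000,
    params: Optional[SimParams] = None,
    cfg: Optional[AssayConfig] = None,
    freqs: Optional[FreqTable] = None,
) -> dict:
    """Empirical mean +- sd of stutter-position height fractions at one STR
    locus over ``n`` simulated single-source samples.

    Fractions come from peaks the caller classified as stutter plus
    stutter-position peaks above the cap, so the estimate is not truncated
    at the interpretation threshold.
    """
    params = params or SimParams()
    cfg = cfg or default_config()
    freqs = freqs or demo_frequency_table()
    fractions = []
    for i in range(n):
        truth = sample_genotype(freqs, rng, params=params)
        table = synthesize(MixtureSpec(primary=truth), params, cfg, rng, sample_id=f"T{i}")
        report = call_sample(table, cfg)
        s = report.str_call(locus)
        for st in s.stutter_peaks:
            fractions.append(st.fraction_of_parent)
        for extra in s.extra_peaks:
            if extra.reason == "stutter_excess" and extra.fraction_of_parent is not None:
                fractions.append(extra.fraction_of_parent)
    arr = np.asarray(fractions)
    return {
        "locus": locus,
        "n": len(arr),
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)),
    }


STUDIES = ("concordance", "mixture_1to10", "mixture_1to20", "ratio_stats", "stutter_stats")


def run_validation_study(
    study: str,
    seed: int,
    n: Optional[int] = None,
    params: Optional[SimParams] = None,
    cfg: Optional[AssayConfig] = None,
    freqs: Optional[FreqTable] = None,
):
    """Run a named in-silico replica of a validation experiment.

    Returns a pandas DataFrame summarising the study (one row per category,
    criterion or locus, as appropriate).
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    if study == "concordance":
        res = concordance_study(rng, params, cfg, freqs)
        rows = [
            {**c, "percent": 100.0 * c["concordant"] / c["n"]} for c in res["categories"]
        ]
        rows.append({"f5": "all", "f2": "all", "n": res["n"],
                     "concordant": res["concordant"], "percent": res["percent"]})
        return pd.DataFrame(rows)
    if study in ("mixture_1to10", "mixture_1to20"):
        ratio = 0.1 if study.endswith("1to10") else 0.05
        res = mixture_study(ratio, rng, n=n or 30, params=params, cfg=cfg, freqs=freqs)
        rows = [{"measure": "detected", "count": res["detected"], "n": res["n"],
                 "percent": res["percent"]}]
        for c, k in res["per_criterion"].items():
            rows.append({"measure": c, "count": k, "n": res["n"],
                         "percent": 100.0 * k / res["n"]})
        return pd.DataFrame(rows)
    if study == "ratio_stats":
        rows = [ratio_stats(locus, rng, n=n or 1000, params=params, cfg=cfg, freqs=freqs)
                for locus in ("F5", "F2")]
        return pd.DataFrame(rows)
    if study == "stutter_stats":
        rows = [stutter_stats(locus, rng, n=n or 1000, params=params, cfg=cfg, freqs=freqs)
                for locus in ("FGA", "SE33")]
        return pd.DataFrame(rows)
    raise ValueError(f"unknown study {study!r} (expected one of {STUDIES})")
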