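"""Declarative model of the multiplex PCR-RFLP assay.

The assay genotypes two thrombophilia variants in one capillary run:

* **FV Leiden** (F5 c.1601G>A) — the variant destroys an MnlI site, so after
  MnlI digestion the wild-type allele yields a short labelled fragment and
  the variant allele a longer one.
* **F2 G20210A** — a mutagenic primer turns the variant into a HindIII site,
  so the variant allele is cut to a shorter fragment while wild type stays
  at full amplicon length.

Two co-amplified controls guard against digestion failure (an FGA intron-1
fragment carrying a mandatory HindIII site, and a mandatory MnlI site inside
the F5 amplicon), and two tetranucleotide STRs (FGA and SE33) provide sample
identity and contamination monitoring.

Everything the genotype caller and the peak simulator need to agree on —
expected fragment sizes per allele, dye channels, STR allele ladders, and
interpretation thresholds — lives in one :class:`AssayConfig`, serialisable
to/from YAML.  The packaged default (``data/default_assay.yaml``) describes
the published assay layout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

import yaml

__all__ = [
    "DYE_CHANNELS",
    "FLUOROCHROME_TO_CHANNEL",
    "ALLELE_LABELS",
    "FragmentRule",
    "StrLocusDef",
    "Thresholds",
    "AssayConfig",
    "ConfigError",
    "load_config",
    "dump_config",
    "default_config",
    "repeats_to_size",
    "str_size_to_repeats",
    "format_allele",
    "parse_allele",
]

#: Channel names of the 5-dye filter set, keyed by conventional colour word.
DYE_CHANNELS = ("blue", "green", "black", "red", "orange")

#: Fluorochrome label -> channel colour on the G5 filter set.
FLUOROCHROME_TO_CHANNEL = {
    "PET": "red",
    "6-FAM": "blue",
    "FAM": "blue",
    "VIC": "green",
    "NED": "black",
    "LIZ": "orange",
}

ALLELE_LABELS = ("wt", "variant", "uncut", "control_cut", "control_uncut")


class ConfigError(ValueError):
    """Raised when an assay configuration violates its invariants."""


@dataclass(frozen=True)
class FragmentRule:
    """One expected fixed-size fragment: a (locus, allele) -> (dye, size) rule.

    ``must_be_absent_after_digestion`` marks the uncut amplicon peaks whose
    persistence reveals a digestion failure.
    """

    locus_id: str
    allele_label: str
    apparent_size: float
    dye: str
    must_be_absent_after_digestion: bool = False

    def __post_init__(self) -> None:
        if self.apparent_size <= 0:
            raise ConfigError(
                f"{self.locus_id}/{self.allele_label}: apparent_size must be > 0, "
                f"got {self.apparent_size}"
            )
        if self.allele_label not in ALLELE_LABELS:
            raise ConfigError(
                f"{self.locus_id}: unknown allele_label {self.allele_label!r} "
                f"(expected one of {ALLELE_LABELS})"
            )
        if self.dye not in DYE_CHANNELS:
            raise ConfigError(
                f"{self.locus_id}/{self.allele_label}: unknown dye {self.dye!r}"
            )
        if self.must_be_absent_after_digestion != (self.allele_label in ("uncut", "control_uncut")):
            raise ConfigError(
                f"{self.locus_id}/{self.allele_label}: must_be_absent_after_digestion "
                "must be set exactly on 'uncut'/'control_uncut' rules"
            )


def _repeat_parts(repeats: float) -> tuple[int, int]:
    """Split a decimal-notation allele into (full repeats, extra bases).

    Forensic convention: allele ``n.p`` means *n* full repeat units plus *p*
    extra bases, p in {1, 2, 3}.  ``22.2`` = 22 repeats + 2 bases.
    """
    n = int(math.floor(repeats + 1e-9))
    p = int(round((repeats - n) * 10))
    if p not in (0, 1, 2, 3):
        raise ValueError(f"invalid microvariant allele {repeats!r}: partial must be .1/.2/.3")
    return n, p


def format_allele(repeats: float) -> str:
    """Render a repeat count as its forensic allele label ('22', '28.2')."""
    n, p = _repeat_parts(repeats)
    return f"{n}.{p}" if p else str(n)


def parse_allele(label: Union[str, float]) -> float:
    """Parse an allele label back to a repeat count on the 0.1 lattice."""
    r = float(label)
    _repeat_parts(r)  # validates the microvariant digit
    return round(r, 1)


@dataclass(frozen=True)
class StrLocusDef:
    """Definition of one STR locus: dye, ladder geometry, observed size window.

    Allele size is linear in repeat content: ``size(r) = size_at_min_repeats +
    bases(r) - bases(min_repeats)`` where ``bases(n.p) = repeat_unit*n + p``
    (microvariant digits count literal bases).  ``uncut_size_shift`` is the
    constant offset of the amplicon when the flanking restriction site is not
    cut (the FGA STR amplicon carries an MnlI site upstream of the repeat).
    """

    locus_id: str
    dye: str
    repeat_unit: int = 4
    min_repeats: float = 0.0
    max_repeats: float = 0.0
    size_at_min_repeats: float = 0.0
    observed_size_min: float = 0.0
    observed_size_max: float = 0.0
    uncut_size_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.dye not in DYE_CHANNELS:
            raise ConfigError(f"{self.locus_id}: unknown dye {self.dye!r}")
        if not self.min_repeats < self.max_repeats:
            raise ConfigError(f"{self.locus_id}: min_repeats must be < max_repeats")
        if not self.observed_size_min < self.observed_size_max:
            raise ConfigError(f"{self.locus_id}: observed size window is empty")
        # the linear ladder map must land on the observed window endpoints
        for r, expected in ((self.min_repeats, self.observed_size_min),
                            (self.max_repeats, self.observed_size_max)):
            if abs(repeats_to_size(self, r) - expected) > 2.0:
                raise ConfigError(
                    f"{self.locus_id}: ladder map gives {repeats_to_size(self, r)} bp at "
                    f"{format_allele(r)} repeats but observed window says {expected} bp"
                )

    def _bases(self, repeats: float) -> int:
        n, p = _repeat_parts(repeats)
        return self.repeat_unit * n + p

    def ladder(self, extend_below: int = 0) -> list[float]:
        """All alleles on the locus ladder (integer + .1/.2/.3 microvariants).

        ``extend_below`` prepends that many full-repeat positions below
        ``min_repeats`` — used to bin stutter peaks of the smallest allele.
        """
        lo = self._bases(self.min_repeats) - extend_below * self.repeat_unit
        hi = self._bases(self.max_repeats)
        out = []
        n_start = int(math.floor(self.min_repeats)) - extend_below - 1
        n_stop = int(math.floor(self.max_repeats)) + 1
        for n in range(max(n_start, 0), n_stop + 1):
            for p in (0, 1, 2, 3):
                b = self.repeat_unit * n + p
                if lo <= b <= hi:
                    out.append(round(n + p / 10, 1))
        return out


def repeats_to_size(locus: StrLocusDef, repeats: float) -> float:
    """Apparent size (bp) of an allele under the locus's linear ladder map."""
    return locus.size_at_min_repeats + locus._bases(repeats) - locus._bases(locus.min_repeats)


def str_size_to_repeats(
    locus: StrLocusDef, size: float, tol: float = 0.5, extend_below: int = 0
) -> Optional[float]:
    """Bin an apparent size to the nearest ladder allele.

    Returns the repeat label (e.g. ``28.2``) or ``None`` when the size is
    off-ladder (no allele within ``tol`` bp) — callers must handle the flag,
    it is not an error.
    """
    best, best_d = None, tol + 1e-9
    for r in locus.ladder(extend_below=extend_below):
        d = abs(repeats_to_size(locus, r) - size)
        if d < best_d:
            best, best_d = r, d
    return best


@dataclass(frozen=True)
class Thresholds:
    """Interpretation thresholds shared by caller, QC and simulator.

    * ``allele_call_rfu`` — minimum peak height for a true allele; set to
      3x the observed fluorescence noise ceiling.
    * ``stutter_max_fraction`` — largest stutter/parent height fraction still
      explained as PCR slippage (mean + 2 SD of the stutter distribution).
    * ``het_ratio_min_f5``/``f2`` — lower bound (mean - 2 SD) on the
      variant/wild-type peak-height ratio of a heterozygote; below it the
      sample is re-tested.
    * ``str_het_ratio_min`` — minimum sister-peak fraction for a
      minus-one-repeat peak to be accepted as a genuine adjacent-repeat
      heterozygote allele rather than suspected contamination.
    """

    allele_call_rfu: float = 150.0
    noise_ceiling_rfu: float = 50.0
    saturation_rfu: float = 32000.0
    stutter_max_fraction: float = 0.11
    het_ratio_min_f5: float = 0.49
    het_ratio_min_f2: float = 0.49
    str_het_ratio_min: float = 0.30
    size_match_tol: float = 1.0
    str_bin_tol: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.stutter_max_fraction < 1:
            raise ConfigError("stutter_max_fraction must be in (0, 1)")
        for name in ("het_ratio_min_f5", "het_ratio_min_f2", "str_het_ratio_min"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"{name} must be in (0, 1)")
        for name in ("allele_call_rfu", "noise_ceiling_rfu", "saturation_rfu",
                     "size_match_tol", "str_bin_tol"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")


@dataclass(frozen=True)
class AssayConfig:
    """The full declarative assay: fragment rules, STR loci, thresholds."""

    fragment_rules: tuple[FragmentRule, ...]
    str_loci: tuple[StrLocusDef, ...]
    thresholds: Thresholds = field(default_factory=Thresholds)

    def __post_init__(self) -> None:
        object.__setattr__(self, "fragment_rules", tuple(self.fragment_rules))
        object.__setattr__(self, "str_loci", tuple(self.str_loci))
        tol = self.thresholds.size_match_tol
        seen: list[FragmentRule] = []
        for rule in self.fragment_rules:
            for other in seen:
                if rule.dye == other.dye and abs(rule.apparent_size - other.apparent_size) <= tol:
                    raise ConfigError(
                        f"fragments {other.locus_id}/{other.allele_label} and "
                        f"{rule.locus_id}/{rule.allele_label} collide on dye "
                        f"{rule.dye} within {tol} bp"
                    )
            seen.append(rule)

    # -- lookups -----------------------------------------------------------

    def rule(self, locus_id: str, allele_label: str) -> FragmentRule:
        for r in self.fragment_rules:
            if r.locus_id == locus_id and r.allele_label == allele_label:
                return r
        raise KeyError(f"no rule for {locus_id}/{allele_label}")

    def str_locus(self, locus_id: str) -> StrLocusDef:
        for s in self.str_loci:
            if s.locus_id == locus_id:
                return s
        raise KeyError(f"no STR locus {locus_id}")

    @property
    def dyes(self) -> dict[str, str]:
        """Mapping locus -> channel, over fixed fragments and STR loci."""
        out = {r.locus_id: r.dye for r in self.fragment_rules}
        out.update({s.locus_id: s.dye for s in self.str_loci})
        return out

    # -- (de)serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "fragment_rules": [asdict(r) for r in self.fragment_rules],
            "str_loci": [asdict(s) for s in self.str_loci],
            "thresholds": asdict(self.thresholds),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AssayConfig":
        try:
            rules = tuple(FragmentRule(**r) for r in d["fragment_rules"])
            loci = tuple(StrLocusDef(**s) for s in d["str_loci"])
            thresholds = Thresholds(**d.get("thresholds", {}))
        except TypeError as exc:
            raise ConfigError(f"malformed config: {exc}") from exc
        except KeyError as exc:
            raise ConfigError(f"missing config section: {exc}") from exc
        return cls(fragment_rules=rules, str_loci=loci, thresholds=thresholds)


def load_config(path: Union[str, Path]) -> AssayConfig:
    """Load and validate an assay configuration from a YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: config document must be a mapping")
    return AssayConfig.from_dict(doc)


def dump_config(cfg: AssayConfig, path: Union[str, Path]) -> None:
    """Serialise a configuration to YAML (round-trips through load_config)."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def default_config() -> AssayConfig:
    """The packaged default configuration describing the published assay."""
    text = resources.files("rflpmux.data").joinpath("default_assay.yaml").read_text()
    return AssayConfig.from_dict(yaml.safe_load(text))
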