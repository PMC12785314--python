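"""In-silico restriction digestion with MnlI and HindIII.

Used to verify the assay's design logic on synthetic amplicons: the FV
Leiden variant destroys an MnlI recognition site (CCTC), while the F2
G20210A variant — combined with a mutagenic primer — creates a HindIII site
(AAGCTT).  Capillary electrophoresis sees denatured, 5'-labelled single
strands, so only the top-strand cut coordinate matters for fragment sizing;
each recognition event therefore contributes a single cut position.

MnlI is a type IIS enzyme cutting downstream of its recognition sequence
(CCTC 7/6); for a site on the bottom strand the top-strand scission lands
*upstream* of the motif, which :func:`find_sites` maps back to top-strand
coordinates.  Cuts whose coordinate falls outside the sequence (site too
close to an end) are dropped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

__all__ = [
    "Enzyme",
    "DigestResult",
    "MNLI",
    "HINDIII",
    "ENZYMES",
    "find_sites",
    "digest_sequence",
]


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme as a recognition motif plus strand cut offsets.

    ``cut_offset_top`` / ``cut_offset_bottom`` are measured in bases
    downstream of the recognition 3' end on the respective strand; negative
    values cut inside the recognition sequence (HindIII A^AGCTT has
    ``cut_offset_top = -5``).
    """

    name: str
    recognition: str
    cut_offset_top: int
    cut_offset_bottom: int
    bidirectional: bool = True

    def __post_init__(self) -> None:
        if not self.recognition:
            raise ValueError(f"{self.name}: empty recognition sequence")
        for base in self.recognition:
            if base not in ambiguous_dna_values:
                raise ValueError(f"{self.name}: invalid IUPAC base {base!r}")

    @property
    def regex(self) -> re.Pattern:
        return re.compile("".join(
            f"[{ambiguous_dna_values[b]}]" if len(ambiguous_dna_values[b]) > 1 else b
            for b in self.recognition
        ))


#: MnlI — CCTC(7/6): top strand cut 7 nt downstream of the recognition 3' end.
MNLI = Enzyme("MnlI", "CCTC", cut_offset_top=7, cut_offset_bottom=6)

#: HindIII — A^AGCTT: palindromic, cuts inside the site.
HINDIII = Enzyme("HindIII", "AAGCTT", cut_offset_top=-5, cut_offset_bottom=-1)

ENZYMES = {e.name: e for e in (MNLI, HINDIII)}


@dataclass(frozen=True)
class DigestResult:
    """Cut positions (0-based inter-base coordinates) and the fragments they
    induce as half-open ``(start, end, length)`` intervals tiling the input."""

    sequence_length: int
    cut_positions: tuple[int, ...]
    fragments: tuple[tuple[int, int, int], ...]


def _validate_seq(seq: str) -> str:
    seq = seq.upper()
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"sequence contains non-ACGT characters: {sorted(bad)}")
    return seq


def find_sites(seq: str, enzyme: Enzyme) -> list[int]:
    """Top-strand cut coordinates of every recognition event in ``seq``.

    Both strands are scanned when the enzyme is bidirectional; overlapping
    occurrences are all reported.  Cuts landing outside ``(0, len(seq))`` are
    dropped (no fragment boundary results from them).
    """
    seq = _validate_seq(seq)
    m = len(enzyme.recognition)
    pattern = enzyme.regex
    cuts: set[int] = set()
    # forward-strand occurrences: cut downstream of the motif 3' end
    pos = 0
    while True:
        hit = pattern.search(seq, pos)
        if hit is None:
            break
        cut = hit.start() + m + enzyme.cut_offset_top
        if 0 < cut < len(seq):
            cuts.add(cut)
        pos = hit.start() + 1
    if enzyme.bidirectional:
        # bottom-strand occurrences appear as the motif's reverse complement;
        # the top-strand scission mirrors the bottom-strand offset
        rc = re.compile(
            "".join(
                f"[{ambiguous_dna_values[b]}]" if len(ambiguous_dna_values[b]) > 1 else b
                for b in str(Seq(enzyme.recognition).reverse_complement())
            )
        )
        pos = 0
        while True:
            hit = rc.search(seq, pos)
            if hit is None:
                break
            cut = hit.start() - enzyme.cut_offset_bottom
            if 0 < cut < len(seq):
                cuts.add(cut)
            pos = hit.start() + 1
    return sorted(cuts)


def digest_sequence(seq: str, enzymes: Union[Enzyme, Iterable[Enzyme]]) -> DigestResult:
    """Co-digest ``seq`` with one or more enzymes.

    Fragments tile the sequence exactly; their lengths always sum to
    ``len(seq)`` (a sequence without sites yields itself as one fragment).
    """
    seq = _validate_seq(seq)
    if isinstance(enzymes, Enzyme):
        enzymes = [enzymes]
    cuts = sorted({c for e in enzymes for c in find_sites(seq, e)})
    bounds = [0, *cuts, len(seq)]
    fragments = tuple(
        (a, b, b - a) for a, b in zip(bounds, bounds[1:]) if b > a
    )
    return DigestResult(
        sequence_length=len(seq),
        cut_positions=tuple(cuts),
        fragments=fragments,
    )
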