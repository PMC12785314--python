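"""Peak-table I/O in a fragment-analysis-export CSV dialect.

One canonical dialect is fixed: comma-separated, UTF-8, required header
``Sample,Run,Dye,Size,Height``.  Dyes are channel colour words (red, blue,
green, black, orange) mapped from fluorochrome names (PET, 6-FAM, VIC,
NED, LIZ).  Sizes are apparent bp with one decimal; heights are integer
RFU.  Off-scale peaks are clipped to the saturation ceiling and flagged,
not rejected.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .assay_config import DYE_CHANNELS, FLUOROCHROME_TO_CHANNEL

__all__ = ["Peak", "PeakTable", "PeakTableError", "read_peak_tables", "write_peak_tables"]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("Sample", "Run", "Dye", "Size", "Height")


class PeakTableError(ValueError):
    """Malformed peak-table file."""


@dataclass(frozen=True)
class Peak:
    """One called peak: dye channel, apparent size (bp), height (RFU)."""

    dye: str
    size: float
    height: int
    saturated: bool = False

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError(f"peak size must be > 0, got {self.size}")
        if self.height < 0:
            raise ValueError(f"peak height must be >= 0, got {self.height}")


@dataclass
class PeakTable:
    """All peaks of one sample in one run, sorted by (dye, size)."""

    sample_id: str
    run_id: str = ""
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: (p.dye, p.size))

    def on_dye(self, dye: str) -> list[Peak]:
        return [p for p in self.peaks if p.dye == dye]


def _normalise_dye(raw: str, line_no: int) -> str:
    dye = str(raw).strip()
    dye = FLUOROCHROME_TO_CHANNEL.get(dye.upper(), dye.lower())
    if dye not in DYE_CHANNELS:
        raise PeakTableError(f"line {line_no}: unknown dye {raw!r}")
    return dye


def read_peak_tables(
    path: Union[str, Path], saturation_rfu: float = 32000.0
) -> list[PeakTable]:
    """Read a peak-table CSV into one :class:`PeakTable` per (Sample, Run).

    Rows with a blank Size are skipped with a warning (fragment-analysis
    exports often carry unsized artefact rows).  Heights above the
    saturation ceiling are clipped and the peak flagged ``saturated``.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in REQUIRED_COLUMNS if c not in header]
        if missing:
            raise PeakTableError(f"{path}: missing required column(s) {missing}")
        groups: dict[tuple[str, str], list[Peak]] = {}
        order: list[tuple[str, str]] = []
        for line_no, row in enumerate(reader, start=2):
            key = (str(row["Sample"]).strip(), str(row["Run"]).strip())
            if key not in groups:
                groups[key] = []
                order.append(key)
            raw_size = (row["Size"] or "").strip()
            if raw_size == "":
                logger.warning("%s line %d: blank Size, row skipped", path, line_no)
                continue
            try:
                size = float(raw_size)
            except ValueError:
                raise PeakTableError(f"{path} line {line_no}: non-numeric Size {raw_size!r}")
            try:
                height = int(round(float(row["Height"])))
            except (TypeError, ValueError):
                raise PeakTableError(
                    f"{path} line {line_no}: non-numeric Height {row['Height']!r}"
                )
            dye = _normalise_dye(row["Dye"], line_no)
            saturated = height > saturation_rfu
            if saturated:
                logger.warning(
                    "%s line %d: off-scale peak clipped to %d RFU", path, line_no,
                    int(saturation_rfu),
                )
                height = int(saturation_rfu)
            groups[key].append(Peak(dye=dye, size=size, height=height, saturated=saturated))
    return [
        PeakTable(sample_id=sample, run_id=run, peaks=groups[(sample, run)])
        for sample, run in order
    ]


def write_peak_tables(tables: Sequence[PeakTable], path: Union[str, Path]) -> None:
    """Write tables to CSV, re-readable by :func:`read_peak_tables`.

    Sizes are printed with one decimal, heights as integers.  A table with
    no peaks contributes no rows (warning logged); an empty list yields a
    header-only file.
    """
    path = Path(path)
    rows = []
    for table in tables:
        if not table.peaks:
            logger.warning("sample %s has no peaks; omitted from %s", table.sample_id, path)
            continue
        for p in table.peaks:
            rows.append(
                {
                    "Sample": table.sample_id,
                    "Run": table.run_id,
                    "Dye": p.dye,
                    "Size": f"{p.size:.1f}",
                    "Height": int(p.height),
                }
            )
    frame = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))
    frame.to_csv(path, index=False)
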