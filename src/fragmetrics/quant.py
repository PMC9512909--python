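"""Assay-level quantitation helpers for multiplex PCR measurements.

The universal quantification panel runs two assays per amplicon length
(on separate chromosomes, as internal copy-number controls). These
helpers average same-length assays into a [long]/[short] fragmentation
ratio, apply the factor-2 qPCR correction for bisulfite-converted DNA
(only the sense strand of a converted duplex amplifies), compute
bisulfite recovery against the diluted input, and normalise each assay
to the mean of its locus for positional-protection comparisons. All
values are proportions internally; format to percent only for display.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AssayRecord",
    "PlexMeasurement",
    "plex_ratio",
    "bisulfite_correct",
    "bisulfite_uncorrect",
    "recovery",
    "ratio_to_mean",
    "read_plex_tsv",
]


@dataclass(frozen=True)
class AssayRecord:
    """One assay's measurement: id, locus, amplicon length, copies/µl."""

    assay: str
    locus: str
    amplicon_bp: int
    copies: float

    def __post_init__(self) -> None:
        if self.copies < 0:
            raise ValueError(f"{self.assay}: copies must be non-negative")
        if self.amplicon_bp < 1:
            raise ValueError(f"{self.assay}: amplicon length must be >= 1 bp")


@dataclass(frozen=True)
class PlexMeasurement:
    """A multiplex measurement: a collection of per-assay records."""

    records: tuple

    def __init__(self, records: Iterable[AssayRecord]) -> None:
        object.__setattr__(self, "records", tuple(records))

    def at_length(self, amplicon_bp: int) -> list[AssayRecord]:
        return [r for r in self.records if r.amplicon_bp == amplicon_bp]

    def at_locus(self, locus: str) -> list[AssayRecord]:
        return [r for r in self.records if r.locus == locus]


def plex_ratio(
    p: PlexMeasurement, long_len: int = 175, short_len: int = 125
) -> float:
    """[long]/[short] ratio: mean copies of the long assays over the short.

    Averaging the two same-length assays first absorbs locus-specific
    noise before the ratio is taken.
    """
    longs = [r.copies for r in p.at_length(long_len)]
    shorts = [r.copies for r in p.at_length(short_len)]
    if not longs or not shorts:
        raise ValueError(
            f"need at least one assay at each of {long_len} and {short_len} bp"
        )
    short_mean = float(np.mean(shorts))
    if short_mean <= 0:
        raise ValueError("mean short-amplicon copies is zero")
    return float(np.mean(longs)) / short_mean


def bisulfite_correct(c_qpcr: float) -> float:
    """Double a qPCR concentration measured on bisulfite-converted DNA.

    Conversion leaves only the sense strand amplifiable, shifting qPCR by
    one cycle threshold versus genomic DNA. Do NOT apply to ddPCR values:
    droplet counting already measures amplifiable molecules absolutely.
    """
    if c_qpcr < 0:
        raise ValueError("concentration must be non-negative")
    return 2.0 * c_qpcr


def bisulfite_uncorrect(c_corrected: float) -> float:
    """Inverse of :func:`bisulfite_correct`."""
    if c_corrected < 0:
        raise ValueError("concentration must be non-negative")
    return c_corrected / 2.0


def recovery(c_converted: float, c_input: float, dilution: float = 1.0) -> float:
    """Proportion of DNA recovered through bisulfite conversion.

    The converted concentration divided by the input concentration at the
    matching dilution factor.
    """
    if c_input <= 0:
        raise ValueError("input concentration must be > 0")
    if dilution <= 0:
        raise ValueError("dilution factor must be > 0")
    if c_converted < 0:
        raise ValueError("converted concentration must be non-negative")
    return c_converted / (c_input / dilution)


def ratio_to_mean(p: PlexMeasurement, locus: str) -> dict[str, float]:
    """Each assay's copies divided by the mean of all assays at its locus.

    The returned ratios average to exactly 1, normalising samples so that
    positional protection effects can be compared across them.
    """
    recs = p.at_locus(locus)
    if len(recs) < 2:
        raise ValueError(f"need >= 2 assays at locus {locus!r}")
    mean = float(np.mean([r.copies for r in recs]))
    if mean <= 0:
        raise ValueError(f"zero mean copies at locus {locus!r}")
    return {r.assay: r.copies / mean for r in recs}


def read_plex_tsv(path) -> dict[str, PlexMeasurement]:
    """Read assay measurements from TSV, one PlexMeasurement per sample.

    Columns: ``sample``, ``assay``, ``locus``, ``amplicon_bp``,
    ``copies_per_ul``.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "assay", "locus", "amplicon_bp", "copies_per_ul"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: needs columns {sorted(required)}")
    out = {}
    for sample, grp in df.groupby("sample"):
        out[str(sample)] = PlexMeasurement(
            AssayRecord(
                assay=str(row.assay),
                locus=str(row.locus),
                amplicon_bp=int(row.amplicon_bp),
                copies=float(row.copies_per_ul),
            )
            for row in grp.itertuples(index=False)
        )
    return out
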