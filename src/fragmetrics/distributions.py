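"""Fragment-size distributions from electrophoresis region tables.

A fragment-size distribution records, for each fragment length (bp), the
mass concentration (pg/µl) of DNA made up of fragments of that length, as
exported from a microfluidic capillary electrophoresis region table
(e.g., a Bioanalyzer smear/region export). These distributions drive the
intact-proportion model: the mass at each length is the genome-equivalent
weight that length class contributes to the sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DistributionError",
    "FragmentSizeDistribution",
    "read_distribution",
    "write_distribution",
    "resample_to_unit_bins",
    "average_fragment_length",
]

#: relative tolerance for mass-conservation guarantees
MASS_RTOL = 1e-9

DEFAULT_LENGTH_COL = "length_bp"
DEFAULT_CONC_COL = "conc_pg_ul"


class DistributionError(ValueError):
    """Invalid fragment-size distribution or distribution table."""


@dataclass(frozen=True)
class FragmentSizeDistribution:
    """Binned mass concentration per integer fragment length.

    Parameters
    ----------
    lengths
        Fragment lengths in bp; strictly increasing positive integers.
    concentrations
        Mass concentration (pg/µl) per length bin, aligned with ``lengths``.
    """

    lengths: np.ndarray
    concentrations: np.ndarray

    def __post_init__(self) -> None:
        lengths = np.asarray(self.lengths, dtype=np.int64)
        concs = np.asarray(self.concentrations, dtype=np.float64)
        object.__setattr__(self, "lengths", lengths)
        object.__setattr__(self, "concentrations", concs)
        if lengths.ndim != 1 or concs.ndim != 1 or lengths.size != concs.size:
            raise DistributionError(
                "lengths and concentrations must be 1-D and aligned"
            )
        if lengths.size == 0:
            raise DistributionError("distribution is empty")
        if np.any(lengths < 1):
            raise DistributionError("fragment lengths must be >= 1 bp")
        if np.any(np.diff(lengths) <= 0):
            raise DistributionError("fragment lengths must be strictly increasing")
        if np.any(concs < 0):
            raise DistributionError("concentrations must be non-negative")
        if not np.all(np.isfinite(concs)):
            raise DistributionError("concentrations must be finite")

    @classmethod
    def from_dict(cls, bins: dict[int, float]) -> "FragmentSizeDistribution":
        """Build from a {length: concentration} mapping (convenience)."""
        lengths = np.array(sorted(bins), dtype=np.int64)
        concs = np.array([bins[int(f)] for f in lengths], dtype=np.float64)
        return cls(lengths, concs)

    @property
    def total_mass(self) -> float:
        """Total mass concentration Σ C_f (pg/µl)."""
        return float(self.concentrations.sum())

    @property
    def shortest(self) -> int:
        """m: shortest fragment length with positive mass."""
        idx = np.flatnonzero(self.concentrations > 0)
        if idx.size == 0:
            raise DistributionError("distribution has no positive mass")
        return int(self.lengths[idx[0]])

    @property
    def longest(self) -> int:
        """n: longest fragment length with positive mass."""
        idx = np.flatnonzero(self.concentrations > 0)
        if idx.size == 0:
            raise DistributionError("distribution has no positive mass")
        return int(self.lengths[idx[-1]])

    def require_mass(self) -> None:
        if self.total_mass <= 0:
            raise DistributionError("distribution has zero total mass")


def read_distribution(
    path,
    length_col: str = DEFAULT_LENGTH_COL,
    conc_col: str = DEFAULT_CONC_COL,
    sep: str | None = None,
) -> FragmentSizeDistribution:
    """Read a fragment-size distribution from a delimited region-table export.

    Rows may be unsorted; non-integer lengths are rounded to the nearest bp
    and rows that land on the same integer length are mass-summed (coarse
    instrument exports can repeat a rounded length).

    Parameters
    ----------
    path
        CSV/TSV file with a header row.
    length_col, conc_col
        Column names for fragment length (bp) and concentration (pg/µl).
    sep
        Field separator; ``None`` sniffs comma vs tab.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    if df.empty:
        raise DistributionError(f"{path}: file has no data rows")
    for col in (length_col, conc_col):
        if col not in df.columns:
            raise DistributionError(
                f"{path}: missing column {col!r} (found {list(df.columns)})"
            )
    lengths = pd.to_numeric(df[length_col], errors="coerce")
    concs = pd.to_numeric(df[conc_col], errors="coerce")
    for name, series in ((length_col, lengths), (conc_col, concs)):
        bad = series.index[series.isna()]
        if len(bad):
            raise DistributionError(
                f"{path}: non-numeric {name!r} at data row {int(bad[0])}"
            )
    neg = concs.index[concs < 0]
    if len(neg):
        raise DistributionError(
            f"{path}: negative concentration at data row {int(neg[0])}"
        )
    rounded = lengths.round().astype(np.int64)
    if (rounded < 1).any():
        row = int(rounded.index[rounded < 1][0])
        raise DistributionError(f"{path}: fragment length < 1 bp at data row {row}")
    merged = concs.groupby(rounded).sum().sort_index()
    return FragmentSizeDistribution(
        merged.index.to_numpy(np.int64), merged.to_numpy(np.float64)
    )


def write_distribution(
    d: FragmentSizeDistribution,
    path,
    length_col: str = DEFAULT_LENGTH_COL,
    conc_col: str = DEFAULT_CONC_COL,
    sep: str = ",",
    unit_bins: bool = False,
) -> None:
    """Write a distribution in the same dialect read_distribution accepts."""
    if unit_bins:
        d = resample_to_unit_bins(d)
    pd.DataFrame({length_col: d.lengths, conc_col: d.concentrations}).to_csv(
        path, sep=sep, index=False
    )


def resample_to_unit_bins(d: FragmentSizeDistribution) -> FragmentSizeDistribution:
    """Resample a coarsely binned distribution to one bin per integer bp.

    Mass density is linearly interpolated between the original bin centres
    over [m, n] and then rescaled so the total mass is conserved (relative
    error below 1e-9). A single-bin distribution is returned unchanged.
    """
    if d.lengths.size < 2:
        return d
    lo, hi = int(d.lengths[0]), int(d.lengths[-1])
    grid = np.arange(lo, hi + 1, dtype=np.int64)
    if grid.size == d.lengths.size:
        return d  # already unit-binned
    density = np.interp(grid, d.lengths, d.concentrations)
    total = density.sum()
    if total <= 0:
        raise DistributionError("cannot resample a zero-mass distribution")
    density *= d.total_mass / total
    return FragmentSizeDistribution(grid, density)


def average_fragment_length(
    d: FragmentSizeDistribution, weighting: str = "number"
) -> float:
    """Average fragment length (bp) of a distribution.

    ``number`` weighting (default) counts each molecule once: since the
    number of molecules at length f is proportional to C_f / f, the mean is
    Σ C_f / Σ (C_f / f). ``mass`` weighting weights by mass: Σ f·C_f / Σ C_f.
    """
    d.require_mass()
    c = d.concentrations
    f = d.lengths.astype(np.float64)
    if weighting == "number":
        return float(c.sum() / (c / f).sum())
    if weighting == "mass":
        return float((f * c).sum() / c.sum())
    raise ValueError(f"unknown weighting {weighting!r} (use 'number' or 'mass')")
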