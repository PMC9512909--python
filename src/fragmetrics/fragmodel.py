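"""Closed-form stochastic fragmentation model.

For a genome broken into fragments of a single length f, a region of
length r survives unbroken with probability (f − r + 1)/f: of the f
possible phases of the fragmentation grid relative to the region,
f − r + 1 leave the region wholly inside one fragment. Real samples
fragment as a distribution of lengths, so the sample-level intact
proportion weights each length class by its mass concentration C_f.
Ratios of intact proportions at two amplicon lengths give the
[long]/[short] fragmentation index measurable by differential-length PCR,
and a genome-mass constant converts mass concentrations to genome copies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .distributions import FragmentSizeDistribution

__all__ = [
    "GenomeMassModel",
    "HUMAN_GENOME",
    "intact_proportion",
    "intact_proportion_distribution",
    "long_short_ratio",
    "mass_to_copies",
    "copies_to_mass",
    "round_sig",
]


@dataclass(frozen=True)
class GenomeMassModel:
    """Constants converting a DNA mass to haploid genome copies.

    genome_mass_pg = genome_length × bp_molar_mass × pg_per_g / avogadro,
    ≈ 3.4917 pg (≈ 3.5 pg at 2 s.f.) with the human defaults.
    """

    genome_length: int = 3_234_830_000  # haploid human genome, bp
    bp_molar_mass: float = 650.0  # g/mol per base pair
    avogadro: float = 6.022e23  # molecules/mol
    pg_per_g: float = 1e12

    def __post_init__(self) -> None:
        for name in ("genome_length", "bp_molar_mass", "avogadro", "pg_per_g"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def genome_mass_pg(self) -> float:
        """Mass of one genome copy in pg (computed, never hard-coded)."""
        return (
            self.genome_length * self.bp_molar_mass * self.pg_per_g / self.avogadro
        )


HUMAN_GENOME = GenomeMassModel()


def _check_region(r, name: str = "r") -> int:
    if isinstance(r, bool) or (not isinstance(r, (int, np.integer)) and r != int(r)):
        raise ValueError(f"{name} must be an integer number of bp, got {r!r}")
    r = int(r)
    if r < 1:
        raise ValueError(f"{name} must be >= 1 bp, got {r}")
    return r


def intact_proportion(r: int, f: int) -> float:
    """Proportion of copies of an r-bp region left intact at fragment length f.

    Returns (f − r + 1)/f for f ≥ r and 0 otherwise (a region longer than
    the fragment cannot survive intact).
    """
    r = _check_region(r, "r")
    f = _check_region(f, "f")
    if f < r:
        return 0.0
    return (f - r + 1) / f


def intact_proportion_distribution(d: FragmentSizeDistribution, r: int) -> float:
    """Mass-weighted intact proportion of an r-bp region in a fragmented sample.

    Σ_{f≥r} ((f − r + 1)/f)·C_f over Σ_f C_f: only fragments at least as
    long as the region contribute intact copies, while every fragment
    contributes to the total mass.
    """
    r = _check_region(r, "r")
    d.require_mass()
    f = d.lengths.astype(np.float64)
    c = d.concentrations
    keep = d.lengths >= r
    numer = float((((f - r + 1.0) / f) * c)[keep].sum())
    return numer / d.total_mass


def long_short_ratio(d: FragmentSizeDistribution, b: int, s: int) -> float:
    """[long]/[short] amplifiable-copy ratio for region lengths b ≥ s.

    Equal to the ratio of distribution-weighted intact proportions at the
    two lengths; lies in [0, 1] when b ≥ s (1 = intact, → 0 with
    increasing fragmentation).
    """
    b = _check_region(b, "b")
    s = _check_region(s, "s")
    denom = intact_proportion_distribution(d, s)
    if denom <= 0:
        raise ValueError(
            f"no amplifiable copies at the short length {s} bp: "
            "all fragments are shorter than the short region"
        )
    return intact_proportion_distribution(d, b) / denom


def mass_to_copies(c: float, model: GenomeMassModel = HUMAN_GENOME) -> float:
    """Convert a mass concentration (pg/µl) to genome copies/µl."""
    if c < 0:
        raise ValueError("mass concentration must be non-negative")
    return c / model.genome_mass_pg


def copies_to_mass(copies: float, model: GenomeMassModel = HUMAN_GENOME) -> float:
    """Convert genome copies/µl to a mass concentration (pg/µl)."""
    if copies < 0:
        raise ValueError("copy concentration must be non-negative")
    return copies * model.genome_mass_pg


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (display helper only)."""
    if x == 0:
        return 0.0
    return round(x, sig - 1 - int(math.floor(math.log10(abs(x)))))
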