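"""Monte Carlo fragmentation oracle and synthetic-data generators.

The simulator realises the sliding-window fragmentation model directly:
a genome is cut every f bp from a uniformly random phase, and a target
region is intact when no cut falls strictly inside it. Averaging over
replicates estimates the closed-form intact proportions, providing an
independent stochastic check of the model. The module also generates the
synthetic inputs the rest of the package is exercised with: sonication-
like unimodal fragment-size distributions, cfDNA-like nucleosome-ladder
distributions, and fragment sets with planted nucleosome positions.

All stochastic operations take a mandatory seed and use numpy's PCG64
generator (``np.random.default_rng``); results are bit-reproducible for a
fixed seed and numpy version.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .distributions import FragmentSizeDistribution
from .protection import FragmentSet

__all__ = [
    "FragmentationExperiment",
    "MonteCarloEstimate",
    "equal_length_fragmentation",
    "mixture_fragmentation",
    "synth_distribution",
    "synth_fragment_set",
]

RNG_ALGORITHM = "numpy.random.PCG64"


@dataclass(frozen=True)
class FragmentationExperiment:
    """A simulated fragmentation experiment targeting one region.

    ``circular`` keeps the cut lattice translation-invariant (no genome
    ends), under which the closed form (f − r + 1)/f is exact; in linear
    mode the same cut lattice applies but fragments are truncated at the
    genome ends, which perturbs *fragment lengths* near the boundary by
    O(f/genome_length) while leaving the intactness of an interior region
    unchanged.
    """

    genome_length: int
    region_start: int
    region_length: int
    replicates: int
    seed: int
    circular: bool = True

    def __post_init__(self) -> None:
        if self.region_length < 1 or self.region_start < 0:
            raise ValueError("region must have positive length and start >= 0")
        if self.region_start + self.region_length > self.genome_length:
            raise ValueError("region does not fit in the genome")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")


@dataclass(frozen=True)
class MonteCarloEstimate:
    """Estimated intact proportion with its binomial standard error."""

    estimate: float
    se: float
    replicates: int
    seed: int
    rng: str = RNG_ALGORITHM


def _intact(phases: np.ndarray, fs: np.ndarray, start: int, r: int) -> np.ndarray:
    """Whether the region [start, start + r) is uncut, per replicate.

    Cuts sit at phase + k·f. The first cut strictly right of ``start`` is
    located explicitly; the region survives iff that cut is at or beyond
    the region's end.
    """
    first_cut = phases + fs * (np.floor_divide(start - phases, fs) + 1)
    return first_cut >= start + r


def equal_length_fragmentation(
    exp: FragmentationExperiment, f: int
) -> MonteCarloEstimate:
    """Estimate the intact proportion of the region at fragment length f."""
    f = int(f)
    if f < 1:
        raise ValueError("fragment length must be >= 1 bp")
    if exp.region_length > exp.genome_length:
        raise ValueError("region longer than genome")
    rng = np.random.default_rng(exp.seed)
    phases = rng.integers(0, f, size=exp.replicates, dtype=np.int64)
    fs = np.full(exp.replicates, f, dtype=np.int64)
    hits = _intact(phases, fs, exp.region_start, exp.region_length)
    p = float(hits.mean())
    se = float(np.sqrt(p * (1.0 - p) / exp.replicates))
    return MonteCarloEstimate(p, se, exp.replicates, exp.seed)


def mixture_fragmentation(
    exp: FragmentationExperiment, d: FragmentSizeDistribution
) -> MonteCarloEstimate:
    """Estimate the sample-level intact proportion for a size distribution.

    Each replicate draws a fragment length with probability proportional
    to its mass concentration C_f (genome-equivalent weighting: a pg of
    200-mers blankets the region as often as a pg of 100-mers), then cuts
    at that length from a random phase.
    """
    d.require_mass()
    rng = np.random.default_rng(exp.seed)
    p_mass = d.concentrations / d.total_mass
    fs = rng.choice(d.lengths, size=exp.replicates, p=p_mass).astype(np.int64)
    phases = (rng.random(exp.replicates) * fs).astype(np.int64)
    hits = _intact(phases, fs, exp.region_start, exp.region_length)
    p = float(hits.mean())
    se = float(np.sqrt(p * (1.0 - p) / exp.replicates))
    return MonteCarloEstimate(p, se, exp.replicates, exp.seed)


def synth_distribution(
    kind: str,
    seed: int,
    mode_bp: int = 300,
    sigma: float = 0.35,
    period: int = 166,
    peak_sd: float = 15.0,
    n_peaks: int = 3,
    total_mass: float = 1000.0,
    min_bp: int = 35,
    max_bp: int = 10_000,
) -> FragmentSizeDistribution:
    """Generate a synthetic fragment-size distribution.

    ``unimodal`` emulates a sonicated-DNA mass profile: a log-normal mass
    density with modal length ``mode_bp`` and log-scale spread ``sigma``,
    truncated to [min_bp, max_bp] and discretized to unit bins.
    ``nucleosome_ladder`` emulates a cfDNA profile: Gaussian peaks at
    ``period``·k bp (k = 1..n_peaks, halving weights), the characteristic
    mono-/di-/tri-nucleosome ladder. Total mass is scaled to
    ``total_mass`` exactly. The seed fixes the (currently deterministic)
    construction for forward compatibility and is recorded nowhere else.
    """
    if total_mass <= 0 or mode_bp < 1 or period < 1 or n_peaks < 1:
        raise ValueError("degenerate generator parameters")
    if sigma <= 0 or peak_sd <= 0 or min_bp < 1 or max_bp <= min_bp:
        raise ValueError("degenerate generator parameters")
    if kind == "unimodal":
        x = np.arange(min_bp, max_bp + 1, dtype=np.float64)
        # log-normal with mode at mode_bp: scale = mode * exp(sigma^2)
        mu = np.log(mode_bp) + sigma**2
        density = np.exp(-((np.log(x) - mu) ** 2) / (2 * sigma**2)) / x
    elif kind == "nucleosome_ladder":
        hi = min(max_bp, period * n_peaks + int(6 * peak_sd))
        x = np.arange(min_bp, hi + 1, dtype=np.float64)
        density = np.zeros_like(x)
        for k in range(1, n_peaks + 1):
            density += 0.5 ** (k - 1) * np.exp(
                -((x - period * k) ** 2) / (2 * peak_sd**2)
            )
    else:
        raise ValueError(f"unknown kind {kind!r}")
    if density.sum() <= 0:
        raise ValueError("generator parameters yield zero mass in range")
    density *= total_mass / density.sum()
    positive = density > 0
    return FragmentSizeDistribution(
        x.astype(np.int64)[positive], density[positive]
    )


def synth_fragment_set(
    genome_length: int,
    nucleosome_positions: list[int],
    protection_strength,
    n_fragments: int,
    seed: int,
    chrom: str = "chrS",
    length_mean: float = 166.0,
    length_sd: float = 10.0,
    jitter: int = 10,
) -> FragmentSet:
    """Generate cfDNA-like fragments with planted nucleosome positions.

    Fragment lengths are ~N(length_mean, length_sd), rounded and clipped
    to [1, genome_length]. Each fragment picks a planted position
    uniformly; with probability equal to that position's protection
    strength it is centred there (midpoint jittered ±``jitter`` bp),
    otherwise its midpoint is uniform over the genome.
    """
    if np.isscalar(protection_strength):
        strengths = np.full(len(nucleosome_positions), float(protection_strength))
    else:
        strengths = np.asarray(protection_strength, dtype=np.float64)
    if len(strengths) != len(nucleosome_positions):
        raise ValueError("one protection strength per nucleosome position")
    if np.any((strengths < 0) | (strengths > 1)):
        raise ValueError("protection strengths must be in [0, 1]")
    positions = np.asarray(nucleosome_positions, dtype=np.int64)
    if np.any((positions < 0) | (positions >= genome_length)):
        raise ValueError("nucleosome positions must lie within the genome")
    rng = np.random.default_rng(seed)
    lengths = np.clip(
        np.rint(rng.normal(length_mean, length_sd, n_fragments)).astype(np.int64),
        1,
        genome_length,
    )
    if positions.size:
        which = rng.integers(0, positions.size, n_fragments)
        protected = rng.random(n_fragments) < strengths[which]
        mids = np.where(
            protected,
            positions[which] + rng.integers(-jitter, jitter + 1, n_fragments),
            rng.integers(0, genome_length, n_fragments),
        )
    else:
        mids = rng.integers(0, genome_length, n_fragments)
    starts = np.clip(mids - lengths // 2, 0, None)
    starts = np.minimum(starts, genome_length - lengths)
    ends = starts + lengths
    return FragmentSet.from_intervals(
        (chrom, int(s), int(e)) for s, e in zip(starts, ends)
    )
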