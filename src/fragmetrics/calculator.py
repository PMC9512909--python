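"""Fragment Calculator: reference-interpolated estimates from a dual assay.

A sample measured with a short (default 125 bp) and a long (default
175 bp) amplicon yields a [long]/[short] ratio that indexes its degree of
fragmentation. Against a panel of reference samples with known
fragment-size distributions — whose own [long]/[short] ratios increase
monotonically with average fragment length — the measured ratio is
bracketed between two reference anchors and linearly interpolated to
estimate:

* intact copies of a region of any length r (via each anchor's
  [short]/[r] ratio),
* total genome copies (the r = 1 case: every fragment contains its
  single-bp regions intact), and
* the sample's average fragment length.

Caveat: FFPE-derived DNA carries single-strand breaks and residual
crosslinks, so it amplifies worse than its size profile predicts; the
calculator does not correct for this.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .distributions import FragmentSizeDistribution, read_distribution
from .fragmodel import intact_proportion_distribution, long_short_ratio

__all__ = [
    "AssayMeasurement",
    "ReferenceProfile",
    "ReferenceSet",
    "InterpolationBracket",
    "RatioOutOfRangeError",
    "bracket",
    "interpolate",
    "estimate_region_copies",
    "estimate_genome_copies",
    "estimate_average_length",
    "load_reference_set",
]


class RatioOutOfRangeError(ValueError):
    """Measured ratio falls outside the reference anchor range."""


@dataclass(frozen=True)
class AssayMeasurement:
    """Measured copies/µl for a short and a long amplicon."""

    c_short: float
    c_long: float
    len_short: int = 125
    len_long: int = 175

    def __post_init__(self) -> None:
        if self.c_short <= 0:
            raise ValueError("short-amplicon concentration must be > 0")
        if self.c_long < 0:
            raise ValueError("long-amplicon concentration must be >= 0")
        if not (self.len_long > self.len_short >= 1):
            raise ValueError("need len_long > len_short >= 1")

    @property
    def measured_ratio(self) -> float:
        """[long]/[short] fragmentation ratio of the sample."""
        return self.c_long / self.c_short


@dataclass(frozen=True)
class ReferenceProfile:
    """A reference sample: fragment-size distribution + average length."""

    name: str
    distribution: FragmentSizeDistribution
    average_length: float

    def __post_init__(self) -> None:
        if self.average_length <= 0:
            raise ValueError(f"{self.name}: average_length must be > 0")
        self.distribution.require_mass()


class ReferenceSet:
    """Ordered reference profiles with their [long]/[short] anchor ratios.

    Profiles are sorted by average length at load; their anchor ratios
    (computed from each distribution) must then be strictly increasing —
    more-intact references retain proportionally more long copies.
    """

    def __init__(
        self,
        profiles: Sequence[ReferenceProfile],
        len_short: int = 125,
        len_long: int = 175,
    ) -> None:
        if len(profiles) < 2:
            raise ValueError("need at least 2 reference profiles")
        self.len_short = int(len_short)
        self.len_long = int(len_long)
        self.profiles = sorted(profiles, key=lambda p: p.average_length)
        self.anchor_ratios = [
            long_short_ratio(p.distribution, self.len_long, self.len_short)
            for p in self.profiles
        ]
        for (r0, p0), (r1, p1) in zip(
            zip(self.anchor_ratios, self.profiles),
            zip(self.anchor_ratios[1:], self.profiles[1:]),
        ):
            if not r0 < r1:
                raise ValueError(
                    "anchor ratios must increase strictly with average "
                    f"fragment length: {p0.name} ({r0:.4f}) !< {p1.name} ({r1:.4f})"
                )


@dataclass(frozen=True)
class InterpolationBracket:
    """Two anchors (x1,y1), (x2,y2) and the line through them.

    ``x`` values are [long]/[short] anchor ratios; ``y`` values are the
    response being interpolated (a [short]/[r] ratio or an average
    length). With ``printed_rounding`` the slope, and the intercept
    derived from the rounded slope, are rounded to 3 decimals before
    evaluation — reproducing hand calculations that carry 3-decimal
    intermediates.
    """

    x1: float
    x2: float
    y1: float
    y2: float
    clamped: bool = False

    def __post_init__(self) -> None:
        if not self.x1 < self.x2:
            raise ValueError("bracket requires x1 < x2")

    def evaluate(self, x: float, printed_rounding: bool = False) -> float:
        slope = (self.y2 - self.y1) / (self.x2 - self.x1)
        if printed_rounding:
            slope = round(slope, 3)
            intercept = round(self.y1 - slope * self.x1, 3)
        else:
            intercept = self.y1 - slope * self.x1
        return slope * x + intercept

    @property
    def slope(self) -> float:
        return (self.y2 - self.y1) / (self.x2 - self.x1)

    @property
    def intercept(self) -> float:
        return self.y1 - self.slope * self.x1


def bracket(refset: ReferenceSet, ratio: float, clamp: bool = False):
    """Locate the adjacent anchor pair whose ratios bracket ``ratio``.

    Returns (index_low, index_high, clamped). An exact anchor hit returns a
    degenerate pair (i, i, False). Out-of-range ratios raise by default;
    with ``clamp`` the terminal pair is returned with the clamped flag set.
    Ratios above 1 are rejected outright: the model guarantees
    [long]/[short] ≤ 1, so such a measurement indicates copy-number
    aberration or measurement error.
    """
    if ratio < 0:
        raise RatioOutOfRangeError("measured ratio must be non-negative")
    if ratio > 1:
        raise RatioOutOfRangeError(
            f"measured [long]/[short] ratio {ratio:.3f} exceeds 1, which the "
            "fragmentation model forbids; check for copy-number aberration "
            "in a target region or a measurement error"
        )
    anchors = refset.anchor_ratios
    for i, a in enumerate(anchors):
        if ratio == a:
            return i, i, False
    if ratio < anchors[0]:
        if clamp:
            return 0, 1, True
        raise RatioOutOfRangeError(
            f"ratio {ratio:.3f} below the most fragmented reference anchor "
            f"({anchors[0]:.3f}); sample is outside the reference range"
        )
    if ratio > anchors[-1]:
        if clamp:
            return len(anchors) - 2, len(anchors) - 1, True
        raise RatioOutOfRangeError(
            f"ratio {ratio:.3f} above the most intact reference anchor "
            f"({anchors[-1]:.3f}); sample is outside the reference range"
        )
    i = next(i for i in range(len(anchors) - 1) if anchors[i] < ratio < anchors[i + 1])
    return i, i + 1, False


def interpolate(
    refset: ReferenceSet,
    ratio: float,
    y_values: Sequence[float],
    clamp: bool = False,
    printed_rounding: bool = False,
) -> float:
    """Interpolate a per-anchor response at a measured ratio."""
    i, j, clamped = bracket(refset, ratio, clamp=clamp)
    if i == j:
        return float(y_values[i])
    if clamped:
        warnings.warn(
            "measured ratio outside reference range; returning the clamped "
            "terminal-bracket extrapolation",
            stacklevel=2,
        )
    br = InterpolationBracket(
        refset.anchor_ratios[i], refset.anchor_ratios[j],
        float(y_values[i]), float(y_values[j]), clamped=clamped,
    )
    return br.evaluate(ratio, printed_rounding=printed_rounding)


def estimate_region_copies(
    m: AssayMeasurement,
    refset: ReferenceSet,
    r: int,
    clamp: bool = False,
    printed_rounding: bool = False,
) -> float:
    """Estimate intact copies/µl of an r-bp region.

    Each anchor contributes its [len_short]/[r] intact-proportion ratio;
    the ratio interpolated at the measured [long]/[short] ratio divides the
    measured short-amplicon concentration.
    """
    r = int(r)
    if r < 1:
        raise ValueError("region length must be >= 1 bp")
    if refset.len_short != m.len_short or refset.len_long != m.len_long:
        raise ValueError(
            "measurement amplicon lengths do not match the reference set's"
        )
    ys = [
        intact_proportion_distribution(p.distribution, m.len_short)
        / intact_proportion_distribution(p.distribution, r)
        for p in refset.profiles
    ]
    ratio = interpolate(
        refset, m.measured_ratio, ys, clamp=clamp, printed_rounding=printed_rounding
    )
    if ratio <= 0:
        raise ValueError(
            f"interpolated [{m.len_short} bp]/[{r} bp] ratio is non-positive; "
            "the measured ratio lies too far outside the model's range"
        )
    return m.c_short / ratio


def estimate_genome_copies(
    m: AssayMeasurement,
    refset: ReferenceSet,
    clamp: bool = False,
    printed_rounding: bool = False,
) -> float:
    """Estimate total genome copies/µl (intact + broken): region length 1 bp."""
    return estimate_region_copies(
        m, refset, 1, clamp=clamp, printed_rounding=printed_rounding
    )


def estimate_average_length(
    m: AssayMeasurement,
    refset: ReferenceSet,
    clamp: bool = False,
    printed_rounding: bool = False,
) -> float:
    """Estimate the sample's average fragment length (bp)."""
    ys = [p.average_length for p in refset.profiles]
    return interpolate(
        refset, m.measured_ratio, ys, clamp=clamp, printed_rounding=printed_rounding
    )


def load_reference_set(
    manifest_path,
    len_short: int = 125,
    len_long: int = 175,
) -> ReferenceSet:
    """Load a reference set from a TSV manifest.

    Columns: ``name``, ``avg_length_bp``, ``distribution_path`` (relative
    paths resolved against the manifest's directory).
    """
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, sep="\t")
    required = {"name", "avg_length_bp", "distribution_path"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{manifest_path}: manifest needs columns {sorted(required)}"
        )
    profiles = []
    for row in df.itertuples(index=False):
        dist_path = Path(row.distribution_path)
        if not dist_path.is_absolute():
            dist_path = manifest_path.parent / dist_path
        profiles.append(
            ReferenceProfile(
                name=str(row.name),
                distribution=read_distribution(dist_path),
                average_length=float(row.avg_length_bp),
            )
        )
    return ReferenceSet(profiles, len_short=len_short, len_long=len_long)
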