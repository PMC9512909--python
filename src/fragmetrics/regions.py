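"""Copy-neutral region selection and cytosine-free assay-site scanning.

Quantification assays placed in regions that undergo somatic copy-number
aberration (CNA) in cancer misreport genome copies, so candidate assay
regions are filtered to the genomic space least affected by CNA: per-base
CNA sample counts are computed from a deduplicated interval collection,
low-count runs are kept (at most ``hard_max`` affected samples, or a
length-weighted percentile), regions poorly covered by the CNA-detection
probe grid are removed (count zero there is uninformative, not neutral),
and for cfDNA assays the survivors are intersected with windows flanking
nucleosome-protection peak apexes. Finally, primer/probe sites that must
amplify bisulfite-converted DNA are restricted to cytosine-free windows
of the template strand, which bisulfite treatment leaves unaltered.

All coordinates are 0-based half-open (BED convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import groupby
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "CoverageTrack",
    "CNARecord",
    "coverage",
    "dedupe_and_filter_records",
    "threshold_low_cna",
    "probe_gap_filter",
    "flank_and_intersect",
    "intersect_intervals",
    "cytosine_free_windows",
    "revcomp",
    "read_bed",
    "write_bed",
    "write_bedgraph",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """BED-style half-open interval with an optional payload."""

    chrom: str
    start: int
    end: int
    payload: object = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CoverageTrack:
    """Run-length encoded per-base counts: (chrom, start, end, count) runs."""

    runs: tuple

    def __post_init__(self) -> None:
        prev = None
        for run in self.runs:
            chrom, start, end, count = run
            if start >= end or count < 0:
                raise ValueError(f"invalid coverage run {run}")
            if prev is not None and prev[0] == chrom:
                if prev[2] > start:
                    raise ValueError("coverage runs overlap or are unsorted")
                if prev[2] == start and prev[3] == count:
                    raise ValueError("adjacent runs with equal count not merged")
            prev = run


def coverage(intervals: Iterable[GenomicInterval]) -> CoverageTrack:
    """Per-base overlap counts of an interval collection, run-length encoded.

    Equivalent to a genome-coverage bedGraph: every base is labelled with
    the number of input intervals covering it, and maximal adjacent runs
    of equal count are merged. Zero-count gaps between covered runs on the
    same chromosome are emitted explicitly.
    """
    by_chrom: dict[str, list] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    runs = []
    for chrom in sorted(by_chrom):
        events: dict[int, int] = {}
        for iv in by_chrom[chrom]:
            events[iv.start] = events.get(iv.start, 0) + 1
            events[iv.end] = events.get(iv.end, 0) - 1
        pos = sorted(events)
        depth = 0
        out: list[list] = []
        for p0, p1 in zip(pos, pos[1:] + [None]):
            depth += events[p0]
            if p1 is None:
                break
            if out and out[-1][3] == depth and out[-1][2] == p0:
                out[-1][2] = p1
            else:
                out.append([chrom, p0, p1, depth])
        runs.extend(tuple(r) for r in out)
    return CoverageTrack(tuple(runs))


@dataclass(frozen=True)
class CNARecord:
    """One CNA call: interval + sample id and completeness/cell-line flags."""

    sample: str
    chrom: str
    start: int
    end: int
    is_cell_line: bool = False
    has_total_cn: bool = True
    has_minor_allele: bool = True


def dedupe_and_filter_records(
    records: Iterable[CNARecord],
) -> tuple[list[GenomicInterval], dict[str, int]]:
    """Clean a CNA record collection before coverage counting.

    Drops cell-line records, records missing total copy number or minor
    allele counts, and duplicate (sample, region) entries; returns the
    kept intervals (payload = sample id) plus per-rule drop counts.
    """
    counts = {"cell_line": 0, "incomplete": 0, "duplicate": 0, "kept": 0}
    seen: set[tuple] = set()
    kept: list[GenomicInterval] = []
    for rec in records:
        if rec.is_cell_line:
            counts["cell_line"] += 1
            continue
        if not (rec.has_total_cn and rec.has_minor_allele):
            counts["incomplete"] += 1
            continue
        key = (rec.sample, rec.chrom, rec.start, rec.end)
        if key in seen:
            counts["duplicate"] += 1
            continue
        seen.add(key)
        kept.append(GenomicInterval(rec.chrom, rec.start, rec.end, rec.sample))
        counts["kept"] += 1
    kept.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return kept, counts


def length_weighted_percentile(track: CoverageTrack, percentile: float) -> int:
    """Per-base percentile of coverage counts (each base weighted equally)."""
    if not 0 < percentile <= 1:
        raise ValueError("percentile must be in (0, 1]")
    counts = np.array([r[3] for r in track.runs], dtype=np.int64)
    lengths = np.array([r[2] - r[1] for r in track.runs], dtype=np.int64)
    order = np.argsort(counts, kind="stable")
    counts, lengths = counts[order], lengths[order]
    cum = np.cumsum(lengths)
    target = percentile * cum[-1]
    idx = int(np.searchsorted(cum, target, side="left"))
    return int(counts[min(idx, len(counts) - 1)])


def threshold_low_cna(
    track: CoverageTrack,
    percentile: float | None = None,
    hard_max: int | None = None,
) -> list[GenomicInterval]:
    """Keep the low-CNA genomic space: runs with at most ``hard_max`` samples.

    ``hard_max`` is the operative published rule (≤ 34 affected samples);
    when only ``percentile`` is given, the cut is derived as the
    length-weighted per-base percentile of counts. Adjacent kept runs are
    merged.
    """
    if not track.runs:
        return []
    if hard_max is None:
        if percentile is None:
            raise ValueError("provide hard_max or percentile")
        hard_max = length_weighted_percentile(track, percentile)
    kept = [
        GenomicInterval(chrom, start, end, count)
        for chrom, start, end, count in track.runs
        if count <= hard_max
    ]
    merged: list[GenomicInterval] = []
    for iv in kept:
        if merged and merged[-1].chrom == iv.chrom and merged[-1].end == iv.start:
            merged[-1] = GenomicInterval(iv.chrom, merged[-1].start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def probe_gap_filter(
    candidates: Sequence[GenomicInterval],
    probes: Mapping[str, Sequence[int]],
    max_gap: int = 10_000,
) -> list[GenomicInterval]:
    """Drop candidates in probe-sparse space.

    A low CNA count where the detection array has no probes is an artefact
    of undetectability, not neutrality. A candidate is dropped when any
    probe-free gap touching it exceeds ``max_gap``: internal gaps between
    consecutive probes whose span intersects the candidate, and each
    candidate edge's distance to its nearest probe. Chromosomes without
    probes lose all their candidates (with a warning).
    """
    sorted_probes = {c: np.sort(np.asarray(p, dtype=np.int64)) for c, p in probes.items()}
    kept = []
    warned: set[str] = set()
    for cand in candidates:
        pos = sorted_probes.get(cand.chrom)
        if pos is None or pos.size == 0:
            if cand.chrom not in warned:
                warnings.warn(
                    f"no probes on {cand.chrom}: dropping all its candidates",
                    stacklevel=2,
                )
                warned.add(cand.chrom)
            continue
        last = cand.end - 1
        left = pos[pos <= cand.start]
        left_gap = cand.start - left[-1] if left.size else int(pos[0]) - cand.start
        right = pos[pos >= last]
        right_gap = right[0] - last if right.size else last - int(pos[-1])
        if left_gap > max_gap or right_gap > max_gap:
            continue
        gaps = np.diff(pos)
        # consecutive-probe spans [pos[i], pos[i+1]] intersecting the candidate
        overlap = (pos[:-1] < cand.end) & (pos[1:] > cand.start)
        if overlap.any() and gaps[overlap].max() > max_gap:
            continue
        kept.append(cand)
    return kept


def intersect_intervals(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Exact interval intersection of two sorted, non-overlapping sets."""
    by_chrom_b: dict[str, list[GenomicInterval]] = {}
    for iv in b:
        by_chrom_b.setdefault(iv.chrom, []).append(iv)
    out = []
    for iv in a:
        for other in by_chrom_b.get(iv.chrom, ()):
            start = max(iv.start, other.start)
            end = min(iv.end, other.end)
            if start < end:
                out.append(GenomicInterval(iv.chrom, start, end))
    out.sort(key=lambda iv: (iv.chrom, iv.start))
    return out


def flank_and_intersect(
    peaks: Sequence[tuple[str, int]],
    regions: Sequence[GenomicInterval],
    flank: int = 65,
) -> list[GenomicInterval]:
    """Window each peak apex by ±``flank`` bp and intersect with regions.

    Each (chrom, apex) becomes [apex − flank, apex + flank + 1): the apex
    base plus ``flank`` bases either side. Windows of nearby apexes are
    unioned first so the result is non-overlapping.
    """
    windows = sorted(
        GenomicInterval(chrom, max(0, apex - flank), apex + flank + 1)
        for chrom, apex in peaks
    )
    merged: list[GenomicInterval] = []
    for iv in windows:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(iv.chrom, merged[-1].start, iv.end)
        else:
            merged.append(iv)
    return intersect_intervals(merged, regions)


def cytosine_free_windows(sequence: str, window: int) -> list[int]:
    """All start offsets of ``window``-bp stretches with no C and no N.

    Cytosine-free template-strand windows amplify identically before and
    after bisulfite conversion; ambiguous bases (N) disqualify a window.
    The scan is strand-agnostic — screen the reverse strand by passing
    ``revcomp(sequence)``.
    """
    if window < 1:
        raise ValueError("window must be >= 1 bp")
    seq = sequence.upper()
    if window > len(seq):
        return []
    bad = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_bad = (bad == ord("C")) | (bad == ord("N"))
    csum = np.concatenate([[0], np.cumsum(is_bad)])
    window_bad = csum[window:] - csum[:-window]
    return [int(s) for s in np.flatnonzero(window_bad == 0)]


def revcomp(sequence: str) -> str:
    """Reverse complement of a DNA sequence (preserves case, keeps N)."""
    return sequence.translate(_COMPLEMENT)[::-1]


def read_bed(path) -> list[GenomicInterval]:
    """Read a BED3+ file into sorted intervals (extra columns → payload)."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {i + 1} has fewer than 3 columns")
            payload = tuple(parts[3:]) if len(parts) > 3 else None
            out.append(
                GenomicInterval(parts[0], int(parts[1]), int(parts[2]), payload)
            )
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            extra = ""
            if iv.payload is not None:
                fields = (
                    iv.payload if isinstance(iv.payload, (tuple, list)) else (iv.payload,)
                )
                extra = "\t" + "\t".join(str(x) for x in fields)
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}{extra}\n")


def write_bedgraph(track: CoverageTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, count in track.runs:
            fh.write(f"{chrom}\t{start}\t{end}\t{count}\n")
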