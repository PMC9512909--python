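"""Independent brute-force oracles shared across the test suite.

Each oracle re-derives a quantity by direct enumeration or per-base
counting, deliberately avoiding the library's own code paths.
"""

from __future__ import annotations

import numpy as np


def brute_wps(frags, region, config):
    """O(positions × fragments) recount of the Windowed Protection Score."""
    w2 = config.window // 2
    rows = [
        (c, int(s), int(e))
        for c, s, e in zip(frags.chroms, frags.starts, frags.ends)
        if c == region.chrom
        and config.min_fragment <= e - s <= config.max_fragment
    ]
    scores = []
    for p in range(region.start, region.end):
        a, b = p - w2, p + w2
        score = 0
        for _, fs, fe in rows:
            if fs <= a and fe >= b:
                score += 1
            elif a < fs < b or a < fe < b:
                score -= 1
        scores.append(score)
    return np.array(scores, dtype=np.int64)


def brute_coverage_array(intervals, chrom, span):
    """Per-base overlap counts for one chromosome over [0, span)."""
    arr = np.zeros(span, dtype=np.int64)
    for iv in intervals:
        if iv.chrom == chrom:
            arr[iv.start : iv.end] += 1
    return arr


def brute_percentile_count(counts, lengths, percentile):
    """Per-base percentile: sorted expanded array, rank ceil(p·N)."""
    expanded = np.sort(np.repeat(counts, lengths))
    rank = int(np.ceil(percentile * expanded.size))
    return int(expanded[max(rank - 1, 0)])


def brute_probe_gap_drop(candidate, probe_positions, max_gap):
    """Re-derive the probe-gap drop decision with plain scans."""
    pos = sorted(probe_positions)
    if not pos:
        return True
    start, last = candidate.start, candidate.end - 1
    lefts = [p for p in pos if p <= start]
    left_gap = start - lefts[-1] if lefts else pos[0] - start
    rights = [p for p in pos if p >= last]
    right_gap = rights[0] - last if rights else last - pos[-1]
    if left_gap > max_gap or right_gap > max_gap:
        return True
    for p0, p1 in zip(pos, pos[1:]):
        if p0 < candidate.end and p1 > candidate.start and p1 - p0 > max_gap:
            return True
    return False


def brute_intersect_mask(intervals, chrom, span):
    """Boolean per-base membership for one chromosome over [0, span)."""
    mask = np.zeros(span, dtype=bool)
    for iv in intervals:
        if iv.chrom == chrom:
            mask[iv.start : iv.end] = True
    return mask


def brute_cytosine_free(sequence, window):
    """Direct window scan for C/N-free starts."""
    seq = sequence.upper()
    return [
        s
        for s in range(len(seq) - window + 1)
        if "C" not in seq[s : s + window] and "N" not in seq[s : s + window]
    ]


def mask_to_intervals(mask, chrom):
    """Convert a boolean per-base mask to sorted half-open (chrom,s,e)."""
    out = []
    in_run = False
    start = 0
    for i, v in enumerate(mask):
        if v and not in_run:
            in_run, start = True, i
        elif not v and in_run:
            out.append((chrom, start, i))
            in_run = False
    if in_run:
        out.append((chrom, start, len(mask)))
    return out
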