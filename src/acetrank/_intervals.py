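"""Internal interval-set helpers shared across modules.

All functions operate on lists of GenomicInterval (or Peak, via .interval)
and use numpy searchsorted over merged sorted intervals, so overlap queries
against a set are O(log n) each.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np

from .io_formats import GenomicInterval, Peak


def as_interval(region) -> GenomicInterval:
    return region.interval if isinstance(region, Peak) else region


def merge_union(regions: Sequence, gap: int = 0) -> list[GenomicInterval]:
    """Union of regions, merging any pair whose gap is <= `gap` (touching merges)."""
    ivs = sorted(
        (as_interval(r) for r in regions), key=lambda r: (r.chrom, r.start, r.end)
    )
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if (
            merged
            and merged[-1].chrom == iv.chrom
            and iv.start - merged[-1].end <= gap
        ):
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(iv.chrom, merged[-1].start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


class IntervalIndex:
    """Query structure over the merged union of a region set."""

    def __init__(self, regions: Sequence):
        by: dict[str, list[tuple[int, int]]] = {}
        for iv in merge_union(regions):
            by.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._by_chrom = {
            c: (np.array([s for s, _ in items]), np.array([e for _, e in items]))
            for c, items in by.items()
        }

    def overlap_bp(self, region) -> int:
        """Total shared span (bp) between `region` and the set union."""
        iv = as_interval(region)
        entry = self._by_chrom.get(iv.chrom)
        if entry is None:
            return 0
        starts, ends = entry
        i0 = int(np.searchsorted(ends, iv.start, side="right"))
        i1 = int(np.searchsorted(starts, iv.end, side="left"))
        if i1 <= i0:
            return 0
        return int(
            np.sum(
                np.minimum(ends[i0:i1], iv.end) - np.maximum(starts[i0:i1], iv.start)
            )
        )

    def overlaps(self, region, min_overlap_bp: int = 1) -> bool:
        return self.overlap_bp(region) >= min_overlap_bp
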