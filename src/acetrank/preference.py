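"""Relative-enrichment preference groups and regulatory-region set algebra.

Regions carrying two acetylation marks (here called mark A, e.g.
H4K5acK8ac, and mark B, e.g. H3K27ac) are classified by the log2 ratio of
their per-kb signal densities into six preference groups:

    group 1:  log2FC <  -2        (most mark-B-preferred)
    group 2:  -2 <= log2FC < -1
    group 3:  -1 <= log2FC <  0
    group 4:   0 <= log2FC <= 1
    group 5:   1 <  log2FC <= 2
    group 6:   log2FC >  2        (most mark-A-preferred)

"Mark-A-preferred" means groups 5-6 (log2FC > 1), "mark-B-preferred" groups
1-2 (log2FC < -1).  Regions are positionally classified as promoters
(anchor within 1 kb of the nearest TSS, boundary inclusive) or enhancers.
"""
from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._intervals import IntervalIndex, as_interval, merge_union
from .io_formats import GenomicInterval, Peak, SignalTrack, TSSAnnotation
from .signal_quant import region_signal

GROUP_A_PREFERRED = (5, 6)
GROUP_B_PREFERRED = (1, 2)


@dataclass(frozen=True)
class PreferenceRecord:
    region: GenomicInterval
    signal_a: float
    signal_b: float
    log2fc: float
    group: int
    position_class: str | None = None  # "promoter" | "enhancer"
    genes: tuple[str, ...] = ()


def classify_preference(
    signal_a: float, signal_b: float, pseudocount: float = 1.0
) -> tuple[float, int]:
    """log2((a + pc)/(b + pc)) and its preference group (1-6)."""
    if signal_a < 0 or signal_b < 0:
        raise ValueError("signals must be non-negative")
    log2fc = math.log2((signal_a + pseudocount) / (signal_b + pseudocount))
    return log2fc, group_of(log2fc)


def group_of(log2fc: float) -> int:
    """Map a log2 fold change to its preference group.

    Boundary assignments follow the printed interval wording: -2 -> group 2,
    -1 -> group 3, 0 and 1 -> group 4, 2 -> group 5.
    """
    if log2fc < -2:
        return 1
    if log2fc < -1:
        return 2
    if log2fc < 0:
        return 3
    if log2fc <= 1:
        return 4
    if log2fc <= 2:
        return 5
    return 6


def classify_position(
    region: GenomicInterval | Peak,
    tss: TSSAnnotation,
    window: int = 1000,
) -> str:
    """'promoter' when the region anchor is within `window` bp of the nearest
    TSS (boundary inclusive), else 'enhancer'."""
    if len(tss) == 0:
        raise ValueError("TSS annotation is empty")
    iv = as_interval(region)
    anchor = region.anchor if isinstance(region, Peak) else iv.midpoint
    hit = tss.nearest(iv.chrom, anchor)
    if hit is None:
        return "enhancer"
    _, dist = hit
    return "promoter" if dist <= window else "enhancer"


def region_universe(
    regions_a: Sequence, regions_b: Sequence
) -> list[GenomicInterval]:
    """Union of two region sets, merging overlapping/touching intervals."""
    return merge_union(list(regions_a) + list(regions_b))


def preference_table(
    universe: Sequence[GenomicInterval],
    track_a: SignalTrack,
    track_b: SignalTrack,
    tss: TSSAnnotation | None = None,
    window: int = 1000,
    pseudocount: float = 1.0,
    input_track: SignalTrack | None = None,
) -> list[PreferenceRecord]:
    """Quantify both marks over each region and classify preference/position."""
    records = []
    for region in universe:
        a = region_signal(track_a, region, input_track).corrected_density
        b = region_signal(track_b, region, input_track).corrected_density
        log2fc, group = classify_preference(a, b, pseudocount)
        pos = classify_position(region, tss, window) if tss is not None else None
        records.append(PreferenceRecord(region, a, b, log2fc, group, pos))
    return records


def records_to_frame(records: Sequence[PreferenceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.region.chrom for r in records],
            "start": [r.region.start for r in records],
            "end": [r.region.end for r in records],
            "signal_a": [r.signal_a for r in records],
            "signal_b": [r.signal_b for r in records],
            "log2fc": [r.log2fc for r in records],
            "group": [r.group for r in records],
            "position_class": [r.position_class for r in records],
            "genes": [";".join(r.genes) for r in records],
        }
    )


def mark_classify_regions(
    h3k4me3_peaks: Sequence[Peak], h3k27ac_peaks: Sequence[Peak]
) -> tuple[list[Peak], list[Peak]]:
    """Promoters = promoter-mark peaks; enhancers = enhancer-mark peaks with
    zero overlap against any promoter peak."""
    promoters = list(h3k4me3_peaks)
    idx = IntervalIndex([p.interval for p in promoters])
    enhancers = [p for p in h3k27ac_peaks if not idx.overlaps(p.interval)]
    return promoters, enhancers


@dataclass(frozen=True)
class SetComparison:
    """Two-way overlap partition of region sets A and B."""

    a_only: tuple[GenomicInterval, ...]
    shared_a: tuple[GenomicInterval, ...]
    b_only: tuple[GenomicInterval, ...]
    shared_b: tuple[GenomicInterval, ...]

    @property
    def n_a(self) -> int:
        return len(self.a_only) + len(self.shared_a)

    @property
    def n_b(self) -> int:
        return len(self.b_only) + len(self.shared_b)

    @property
    def fraction_shared_a(self) -> float:
        return len(self.shared_a) / self.n_a if self.n_a else float("nan")

    @property
    def fraction_shared_b(self) -> float:
        return len(self.shared_b) / self.n_b if self.n_b else float("nan")

    def summary(self) -> dict:
        return {
            "n_a": self.n_a,
            "n_b": self.n_b,
            "n_a_only": len(self.a_only),
            "n_shared_a": len(self.shared_a),
            "n_b_only": len(self.b_only),
            "n_shared_b": len(self.shared_b),
            "fraction_a_only": 1.0 - self.fraction_shared_a if self.n_a else None,
            "fraction_shared_a": self.fraction_shared_a if self.n_a else None,
            "fraction_b_only": 1.0 - self.fraction_shared_b if self.n_b else None,
            "fraction_shared_b": self.fraction_shared_b if self.n_b else None,
        }


def compare_sets(
    set_a: Sequence, set_b: Sequence, min_overlap_bp: int = 1
) -> SetComparison:
    """Partition each side into set-exclusive and shared regions (>= min bp)."""
    ivs_a = [as_interval(r) for r in set_a]
    ivs_b = [as_interval(r) for r in set_b]
    idx_b = IntervalIndex(ivs_b)
    idx_a = IntervalIndex(ivs_a)
    shared_a = tuple(r for r in ivs_a if idx_b.overlaps(r, min_overlap_bp))
    a_only = tuple(r for r in ivs_a if not idx_b.overlaps(r, min_overlap_bp))
    shared_b = tuple(r for r in ivs_b if idx_a.overlaps(r, min_overlap_bp))
    b_only = tuple(r for r in ivs_b if not idx_a.overlaps(r, min_overlap_bp))
    return SetComparison(a_only, shared_a, b_only, shared_b)


def multi_sample_overlap(
    sets: Mapping[str, Sequence],
) -> dict[str, Counter]:
    """Element-wise Venn partition across >= 2 named region sets.

    For each region of each reference set, the membership signature is the
    frozenset of set names it overlaps (>= 1 bp, always including its own).
    Counts are per reference set, so totals per set equal set sizes.
    """
    if len(sets) < 2:
        raise ValueError("multi_sample_overlap needs at least 2 sets")
    indexes = {name: IntervalIndex([as_interval(r) for r in regs]) for name, regs in sets.items()}
    result: dict[str, Counter] = {}
    for name, regs in sets.items():
        counter: Counter = Counter()
        for r in regs:
            signature = frozenset(
                other
                for other, idx in indexes.items()
                if other == name or idx.overlaps(as_interval(r))
            )
            counter[signature] += 1
        result[name] = counter
    return result
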