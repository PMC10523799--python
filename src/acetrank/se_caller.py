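"""Super-enhancer identification by rank ordering of stitched enhancer signal.

The procedure is the classic three-step one: (1) peaks within a stitching
distance (default 12.5 kb) of each other are merged into candidate enhancer
regions, (2) regions are ranked by their input-corrected summed signal, and
(3) the super-enhancer / typical-enhancer boundary is placed geometrically
on the ascending rank-signal curve at the point where a line of slope
(max - min) / N -- i.e. slope 1 after scaling both axes to [0, 1] -- leaves
the fewest points strictly below it.  Everything above that signal level is
a super-enhancer (SE); everything at or below it is a typical enhancer (TE).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._intervals import IntervalIndex
from .io_formats import GenomicInterval, Peak, SignalTrack, TSSAnnotation
from .signal_quant import region_signal


@dataclass
class StitchedRegion:
    """A stitched enhancer: the spanning interval plus its constituent peaks."""

    interval: GenomicInterval
    constituents: tuple[Peak, ...]
    signal: float | None = None  # input-corrected summed signal (raw scale)
    density: float | None = None  # input-corrected per-kb density
    rank: int | None = None  # 1 = highest signal
    label: str | None = None  # "SE" or "TE"

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


def stitch(
    peaks: Sequence[Peak],
    stitch_distance: int = 12500,
    tss_exclusion: TSSAnnotation | None = None,
    tss_window: int = 2500,
) -> list[StitchedRegion]:
    """Merge peaks whose gap is <= stitch_distance into candidate enhancers.

    When `tss_exclusion` is given, peaks fully contained in any
    [TSS - tss_window, TSS + tss_window] interval are removed before
    stitching (the promoter-exclusion option of the reference caller).
    """
    if stitch_distance < 0:
        raise ValueError("stitch_distance must be >= 0")
    kept = list(peaks)
    if tss_exclusion is not None:
        kept = [
            p
            for p in kept
            if not _contained_in_tss_window(p, tss_exclusion, tss_window)
        ]
    kept.sort(key=lambda p: (p.chrom, p.start, p.end))
    regions: list[StitchedRegion] = []
    current: list[Peak] = []
    cur_end = 0
    for p in kept:
        if current and p.chrom == current[0].chrom and p.start - cur_end <= stitch_distance:
            current.append(p)
            cur_end = max(cur_end, p.end)
        else:
            if current:
                regions.append(_finish(current))
            current = [p]
            cur_end = p.end
    if current:
        regions.append(_finish(current))
    return regions


def _finish(peaks: list[Peak]) -> StitchedRegion:
    start = min(p.start for p in peaks)
    end = max(p.end for p in peaks)
    return StitchedRegion(GenomicInterval(peaks[0].chrom, start, end), tuple(peaks))


def _contained_in_tss_window(peak: Peak, tss: TSSAnnotation, window: int) -> bool:
    positions = tss.positions(peak.chrom)
    if positions.size == 0:
        return False
    # containment in [t - w, t + w] requires t in [end - w, start + w]
    lo, hi = peak.end - window, peak.start + window
    if lo > hi:
        return False
    i = int(np.searchsorted(positions, lo, side="left"))
    return i < positions.size and positions[i] <= hi


def geometric_cutoff(signals: Sequence[float]) -> tuple[float, int]:
    """Scaled tangent-slope-1 cutoff on the ascending rank-signal curve.

    Sort signals ascending (negatives floored to 0).  With s = (max - min)/N,
    for every candidate index x count the points lying strictly below the
    line of slope s through (x, v[x]); the cutoff is the candidate minimising
    that count (ties -> smallest index, which gives the lower cutoff and the
    larger SE set).  Returns (cutoff_signal, cutoff_index) with the index
    1-based in the ascending order.  When all values are equal the cutoff is
    that value and nothing exceeds it (no SEs).
    """
    v = np.maximum(np.asarray(signals, dtype=float), 0.0)
    n = v.size
    if n < 2:
        raise ValueError("geometric_cutoff needs at least 2 values")
    v = np.sort(v)
    if v[-1] == v[0]:
        return float(v[-1]), n
    slope = (v[-1] - v[0]) / n
    idx = np.arange(n)
    best_count = None
    best_x = 0
    # chunk candidates to bound memory at ~chunk*n floats
    chunk = max(1, int(4_000_000 // n))
    for x0 in range(0, n, chunk):
        x = idx[x0 : x0 + chunk]
        # line value at i for candidate x: v[x] + slope*(i - x)
        below = v[None, :] < (v[x][:, None] + slope * (idx[None, :] - x[:, None]))
        counts = below.sum(axis=1)
        j = int(np.argmin(counts))
        if best_count is None or counts[j] < best_count:
            best_count = int(counts[j])
            best_x = x0 + j
    return float(v[best_x]), best_x + 1


@dataclass
class SECallResult:
    """Ranked stitched regions with the SE/TE cutoff.

    `regions` is sorted ascending by signal; every region with signal
    strictly above `cutoff_signal` is labelled SE.
    """

    regions: list[StitchedRegion]
    cutoff_signal: float
    cutoff_index: int  # 1-based position of the cutoff in the ascending order

    @property
    def signals(self) -> np.ndarray:
        return np.array([r.signal for r in self.regions], dtype=float)

    @property
    def labels(self) -> list[str]:
        return [r.label or "" for r in self.regions]

    def superenhancers(self) -> list[StitchedRegion]:
        return [r for r in self.regions if r.label == "SE"]

    def typical_enhancers(self) -> list[StitchedRegion]:
        return [r for r in self.regions if r.label == "TE"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [r.chrom for r in self.regions],
                "start": [r.start for r in self.regions],
                "end": [r.end for r in self.regions],
                "n_constituents": [len(r.constituents) for r in self.regions],
                "signal": self.signals,
                "density": [r.density for r in self.regions],
                "rank": [r.rank for r in self.regions],
                "label": self.labels,
                "cutoff_signal": self.cutoff_signal,
            }
        )

    def summary(self) -> dict:
        return {
            "n_regions": len(self.regions),
            "n_superenhancers": len(self.superenhancers()),
            "cutoff_signal": round(self.cutoff_signal, 6),
            "cutoff_index": self.cutoff_index,
        }


def call_superenhancers(
    peaks: Sequence[Peak],
    sample_track: SignalTrack,
    input_track: SignalTrack | None = None,
    stitch_distance: int = 12500,
    tss_exclusion: TSSAnnotation | None = None,
    tss_window: int = 2500,
) -> SECallResult:
    """Stitch, rank by input-corrected summed signal, and label SE/TE."""
    regions = stitch(peaks, stitch_distance, tss_exclusion, tss_window)
    if len(regions) < 2:
        raise ValueError(
            f"need at least 2 stitched regions to place a cutoff, got {len(regions)}"
        )
    for r in regions:
        rs = region_signal(sample_track, r.interval, input_track)
        r.signal = rs.corrected_raw
        r.density = rs.corrected_density
    # deterministic ascending order (ties broken by coordinate)
    regions.sort(key=lambda r: (r.signal, r.chrom, r.start))
    cutoff_signal, cutoff_index = geometric_cutoff([r.signal for r in regions])
    n = len(regions)
    for pos, r in enumerate(regions):
        r.rank = n - pos
        r.label = "SE" if r.signal > cutoff_signal else "TE"
    return SECallResult(regions, cutoff_signal, cutoff_index)


def reproducible_peaks(rep1: Sequence[Peak], rep2: Sequence[Peak]) -> list[Peak]:
    """Reproducible peaks across biological replicates, signals averaged.

    A replicate-1 peak is reproducible when it overlaps (>= 1 bp) any
    replicate-2 peak; its signal becomes the mean of its own signal and the
    replicate-2 signal averaged over overlapping peaks.
    """
    idx = IntervalIndex([p.interval for p in rep2])
    by_chrom: dict[str, list[Peak]] = {}
    for p in rep2:
        by_chrom.setdefault(p.chrom, []).append(p)
    out: list[Peak] = []
    for p in rep1:
        if not idx.overlaps(p.interval):
            continue
        partners = [
            q
            for q in by_chrom.get(p.chrom, [])
            if q.start < p.end and p.start < q.end
        ]
        partner_signal = float(np.mean([q.signal for q in partners]))
        out.append(
            Peak(
                p.interval,
                summit=p.summit,
                signal=(p.signal + partner_signal) / 2.0,
                score_q=p.score_q,
                name=p.name,
            )
        )
    return out
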