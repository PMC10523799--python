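"""Signal quantification over regions and summit-centred profile matrices.

Region signal follows the reads-over-input convention used for enhancer
ranking: densities are per-kb read coverage, input correction is density
subtraction floored at zero, and coverage tracks are library-scaled to reads
per million (RPM) before any cross-sample arithmetic.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import GenomicInterval, SignalTrack


@dataclass(frozen=True)
class RegionSignal:
    """Coverage summary for one region.

    raw               -- summed per-base coverage over the region
    density           -- raw divided by region length in kb
    corrected_density -- sample density minus input density, floored at 0
                         (equals density when no input track was supplied)
    """

    region: GenomicInterval
    raw: float
    density: float
    corrected_density: float

    @property
    def corrected_raw(self) -> float:
        """Input-corrected signal back on the raw (summed-coverage) scale."""
        return self.corrected_density * self.region.length / 1000.0


def region_signal(
    track: SignalTrack,
    region: GenomicInterval,
    input_track: SignalTrack | None = None,
) -> RegionSignal:
    if region.length <= 0:
        raise ValueError("region must have positive length")
    raw = track.integral(region.chrom, region.start, region.end)
    kb = region.length / 1000.0
    density = raw / kb
    if input_track is None:
        corrected = density
    else:
        input_density = input_track.integral(region.chrom, region.start, region.end) / kb
        corrected = max(0.0, density - input_density)
    return RegionSignal(region, raw, density, corrected)


def rpm_scale(track: SignalTrack, library_size: float) -> SignalTrack:
    """Scale run values to reads-per-million for the given library size."""
    if library_size <= 0:
        raise ValueError(f"library_size must be > 0, got {library_size}")
    return track.scale(1e6 / library_size)


@dataclass(frozen=True)
class ProfileMatrix:
    """Anchor x bin matrix of mean coverage around anchors (anchor +/- flank)."""

    values: np.ndarray  # shape (n_anchors, 2*flank/bin_width)
    flank: int
    bin_width: int

    @property
    def offsets(self) -> np.ndarray:
        """Left edge of each bin relative to the anchor."""
        return np.arange(-self.flank, self.flank, self.bin_width)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, columns=self.offsets)
        df.to_csv(path, sep="\t", index=False)


def profile_matrix(
    track: SignalTrack,
    anchors: Sequence[tuple[str, int]],
    flank: int = 5000,
    bin_width: int = 50,
) -> ProfileMatrix:
    """Mean coverage per fixed-width bin around each anchor position.

    Bins extending past the chromosome start contribute zero coverage.
    Anchors on chromosomes absent from the track give all-zero rows.
    """
    if flank % bin_width != 0:
        raise ValueError("flank must be divisible by bin_width")
    n_bins = 2 * flank // bin_width
    rows = np.zeros((len(anchors), n_bins), dtype=float)
    rel_edges = np.arange(-flank, flank + 1, bin_width, dtype=np.int64)
    for i, (chrom, pos) in enumerate(anchors):
        edges = np.maximum(pos + rel_edges, 0)
        f = track.cumulative_at(chrom, edges)
        rows[i] = np.diff(f) / bin_width
    return ProfileMatrix(rows, flank, bin_width)


def meta_profile(matrix: ProfileMatrix) -> np.ndarray:
    """Column-wise mean of a profile matrix (the meta-profile curve)."""
    if matrix.values.shape[0] == 0:
        raise ValueError("meta_profile of an empty matrix")
    return matrix.values.mean(axis=0)
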