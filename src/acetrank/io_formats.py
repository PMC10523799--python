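"""Readers/writers for the genomic text formats the pipeline consumes.

All coordinates are 0-based half-open (BED convention) internally; TSS
positions are single base-pair coordinates on that axis.  Chromosome names
are matched by exact string equality everywhere -- no "chr" aliasing.
"""
from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

STRANDS = ("+", "-", ".")


class ParseError(ValueError):
    """Raised for malformed input lines; message names file and line number."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open 0-based genomic region."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must be > start ({self.start})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """A called peak: an interval plus optional summit and enrichment scores."""

    interval: GenomicInterval
    summit: int | None = None
    signal: float = 0.0
    score_q: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValueError(f"signal must be >= 0, got {self.signal}")
        if self.summit is not None and not (
            self.interval.start <= self.summit < self.interval.end
        ):
            raise ValueError(
                f"summit {self.summit} outside [{self.interval.start}, {self.interval.end})"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def anchor(self) -> int:
        """Summit when present, else the interval midpoint."""
        return self.summit if self.summit is not None else self.interval.midpoint


@dataclass(frozen=True)
class TSSRecord:
    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"tss must be >= 0, got {self.tss}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")


class TSSAnnotation:
    """Collection of transcription start sites with per-chromosome position index."""

    def __init__(self, records: Iterable[TSSRecord]):
        self.records: list[TSSRecord] = list(records)
        ids = [r.gene_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({g for g in ids if ids.count(g) > 1})
            raise ValueError(f"duplicate gene_id(s): {dupes[:5]}")
        self._by_chrom: dict[str, tuple[np.ndarray, list[TSSRecord]]] = {}
        by: dict[str, list[TSSRecord]] = {}
        for r in self.records:
            by.setdefault(r.chrom, []).append(r)
        for chrom, recs in by.items():
            recs.sort(key=lambda r: (r.tss, r.gene_id))
            self._by_chrom[chrom] = (np.array([r.tss for r in recs]), recs)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[TSSRecord]:
        return iter(self.records)

    def positions(self, chrom: str) -> np.ndarray:
        entry = self._by_chrom.get(chrom)
        return entry[0] if entry is not None else np.array([], dtype=int)

    def nearest(self, chrom: str, pos: int) -> tuple[TSSRecord, int] | None:
        """Nearest TSS to `pos`; ties broken by lexicographically smaller gene_id.

        Returns (record, unsigned distance) or None when the chromosome has no genes.
        """
        entry = self._by_chrom.get(chrom)
        if entry is None:
            return None
        positions, recs = entry
        i = int(np.searchsorted(positions, pos))
        candidates = []
        for j in (i - 1, i, i + 1):
            if 0 <= j < len(recs):
                candidates.append((abs(recs[j].tss - pos), recs[j].gene_id, recs[j]))
        dist, _, rec = min(candidates)
        return rec, dist

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TSSAnnotation":
        df = pd.read_csv(path, sep="\t")
        required = {"gene_id", "chrom", "tss", "strand"}
        missing = required - set(df.columns)
        if missing:
            raise ParseError(f"{path}: missing TSS columns {sorted(missing)}")
        return cls(
            TSSRecord(str(r.gene_id), str(r.chrom), int(r.tss), str(r.strand))
            for r in df.itertuples()
        )

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            [(r.gene_id, r.chrom, r.tss, r.strand) for r in self.records],
            columns=["gene_id", "chrom", "tss", "strand"],
        )
        df.to_csv(path, sep="\t", index=False)


class SignalTrack:
    """Piecewise-constant per-base coverage, stored as sorted non-overlapping runs.

    Queries outside any run return 0.  Backed by per-chromosome numpy arrays
    with a cumulative integral so that arbitrary-range sums are O(log n).
    """

    def __init__(self, runs_by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        # runs_by_chrom: chrom -> (starts, ends, values), already validated
        self._runs = runs_by_chrom
        self._cum: dict[str, np.ndarray] = {}
        for chrom, (s, e, v) in runs_by_chrom.items():
            self._cum[chrom] = np.concatenate([[0.0], np.cumsum(v * (e - s))])

    @classmethod
    def from_runs(
        cls, runs: Iterable[tuple[str, int, int, float]], merge_equal: bool = True
    ) -> "SignalTrack":
        by: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in runs:
            if end <= start:
                raise ValueError(f"run end ({end}) must be > start ({start})")
            if start < 0:
                raise ValueError(f"run start must be >= 0, got {start}")
            if value < 0:
                raise ValueError(f"run value must be >= 0, got {value}")
            by.setdefault(chrom, []).append((start, end, float(value)))
        out: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, items in by.items():
            items.sort()
            merged: list[list[float]] = []
            prev_end = -1
            for start, end, value in items:
                if start < prev_end:
                    raise ValueError(
                        f"overlapping runs on {chrom}: run starting at {start} "
                        f"overlaps previous run ending at {prev_end}"
                    )
                if (
                    merge_equal
                    and merged
                    and merged[-1][1] == start
                    and merged[-1][2] == value
                ):
                    merged[-1][1] = end
                else:
                    merged.append([start, end, value])
                prev_end = end
            keep = [m for m in merged if m[2] != 0.0]
            out[chrom] = (
                np.array([m[0] for m in keep], dtype=np.int64),
                np.array([m[1] for m in keep], dtype=np.int64),
                np.array([m[2] for m in keep], dtype=float),
            )
        return cls(out)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._runs)

    def runs(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._runs.get(
            chrom,
            (np.array([], dtype=np.int64), np.array([], dtype=np.int64), np.array([], dtype=float)),
        )

    def cumulative_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """F(x) = integral of the track over [0, x), vectorized over positions."""
        starts, ends, values = self.runs(chrom)
        if starts.size == 0:
            return np.zeros(len(positions), dtype=float)
        cum = self._cum[chrom]
        pos = np.asarray(positions, dtype=np.int64)
        i = np.searchsorted(ends, pos, side="right")  # first run not fully before pos
        base = cum[i]
        inside = i < len(starts)
        partial = np.zeros(len(pos), dtype=float)
        ii = i[inside]
        partial[inside] = values[ii] * np.maximum(0, pos[inside] - starts[ii])
        return base + partial

    def integral(self, chrom: str, start: int, end: int) -> float:
        """Sum of per-base coverage over [start, end)."""
        if end <= start:
            raise ValueError("integral over empty or inverted range")
        f = self.cumulative_at(chrom, np.array([max(start, 0), max(end, 0)]))
        return float(f[1] - f[0])

    def scale(self, factor: float) -> "SignalTrack":
        return SignalTrack(
            {c: (s, e, v * factor) for c, (s, e, v) in self._runs.items()}
        )

    def total(self) -> float:
        return float(sum(self._cum[c][-1] for c in self._runs))

    def to_bedgraph(self, path: str | Path, precision: int = 6) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self._runs):
                starts, ends, values = self._runs[chrom]
                for s, e, v in zip(starts, ends, values):
                    fh.write(f"{chrom}\t{s}\t{e}\t{round(float(v), precision):g}\n")


def _data_lines(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split()


def read_narrowpeak(path: str | Path) -> list[Peak]:
    """Read an ENCODE narrowPeak (10-column) file.

    Column 7 maps to signal, column 9 to the -log10 q-value, column 10 is the
    summit offset from start (-1 means no summit).
    """
    peaks: list[Peak] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 10:
            raise ParseError(
                f"{path}:{lineno}: expected 10 narrowPeak columns, got {len(fields)}"
            )
        try:
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3]
            strand = fields[5] if fields[5] in STRANDS else "."
            signal = float(fields[6])
            score_q = float(fields[8])
            offset = int(fields[9])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        try:
            interval = GenomicInterval(chrom, start, end, strand)
            summit = start + offset if offset >= 0 else None
            peaks.append(
                Peak(
                    interval,
                    summit=summit,
                    signal=signal,
                    score_q=score_q if score_q >= 0 else None,
                    name=name,
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+; strand is taken from column 6 when present."""
    intervals: list[GenomicInterval] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
        strand = fields[5] if len(fields) >= 6 and fields[5] in STRANDS else "."
        try:
            intervals.append(GenomicInterval(fields[0], start, end, strand))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return intervals


def read_bedgraph(path: str | Path) -> SignalTrack:
    """Read a 4-column bedGraph into a SignalTrack; overlapping runs are an error."""
    runs: list[tuple[str, int, int, float]] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 4:
            raise ParseError(f"{path}:{lineno}: expected 4 bedGraph columns")
        try:
            runs.append((fields[0], int(fields[1]), int(fields[2]), float(fields[3])))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
    try:
        return SignalTrack.from_runs(runs)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_bed(
    regions: Sequence[GenomicInterval | Peak],
    path: str | Path,
    extra_columns: Sequence[Sequence] | None = None,
) -> None:
    """Write regions as BED6 (name='.', score=0) in deterministic sorted order.

    `extra_columns`, when given, is one row of extra fields per region (kept in
    the sorted order of the regions).
    """
    ivs = [r.interval if isinstance(r, Peak) else r for r in regions]
    if extra_columns is not None and len(extra_columns) != len(ivs):
        raise ValueError("extra_columns length must match regions")
    order = sorted(
        range(len(ivs)), key=lambda i: (ivs[i].chrom, ivs[i].start, ivs[i].end)
    )
    with open(path, "w") as fh:
        for i in order:
            iv = ivs[i]
            row = [iv.chrom, str(iv.start), str(iv.end), ".", "0", iv.strand]
            if extra_columns is not None:
                row.extend(str(x) for x in extra_columns[i])
            fh.write("\t".join(row) + "\n")


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a gene x sample count table (TSV, first column gene_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ParseError(f"{path}: duplicate gene ids in count table")
    if (df.values < 0).any():
        raise ParseError(f"{path}: negative counts")
    return df


def write_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")
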