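"""Quadrant odds-ratio association between two signals and factor coverage.

The quadrant analysis dichotomises two paired signals (e.g. a co-activator's
binding level and an acetylation mark) at per-signal thresholds, forms the
2x2 strong/weak table, and reports the sample odds ratio with a two-sided
Fisher exact p-value testing OR = 1.  The two-sided p uses the
probability-mass rule: the sum of hypergeometric outcomes (at fixed margins)
whose probability does not exceed that of the observed table.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ._intervals import IntervalIndex, as_interval
from .io_formats import SignalTrack
from .preference import PreferenceRecord
from .signal_quant import region_signal


def quadrant_table(
    signal_x: Sequence[float],
    signal_y: Sequence[float],
    thresh_x: float,
    thresh_y: float,
) -> np.ndarray:
    """2x2 counts [[strong/strong, strong/weak], [weak/strong, weak/weak]].

    "Strong" means >= threshold in the respective signal.
    """
    x = np.asarray(signal_x, dtype=float)
    y = np.asarray(signal_y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("signal_x and signal_y must have the same length")
    sx = x >= thresh_x
    sy = y >= thresh_y
    return np.array(
        [
            [int(np.sum(sx & sy)), int(np.sum(sx & ~sy))],
            [int(np.sum(~sx & sy)), int(np.sum(~sx & ~sy))],
        ]
    )


def _log_comb(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def fisher_exact_p(table: np.ndarray) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration.

    Probability-mass rule with the customary (1 + 1e-7) relative guard
    against floating-point ties.
    """
    (n11, n12), (n21, n22) = np.asarray(table, dtype=np.int64)
    r1, r2 = n11 + n12, n21 + n22
    c1 = n11 + n21
    n = r1 + r2
    if n == 0:
        raise ValueError("all-zero table")
    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    logpmf = np.array(
        [
            _log_comb(r1, a) + _log_comb(r2, c1 - a) - _log_comb(n, c1)
            for a in support
        ]
    )
    pmf = np.exp(logpmf)
    p_obs = pmf[n11 - lo]
    return float(min(1.0, np.sum(pmf[pmf <= p_obs * (1 + 1e-7)])))


@dataclass(frozen=True)
class OddsRatioResult:
    table: np.ndarray
    odds_ratio: float
    p_value: float
    thresholds: tuple[float, float] | None = None

    def summary(self) -> dict:
        return {
            "table": self.table.tolist(),
            "odds_ratio": None if math.isnan(self.odds_ratio) else self.odds_ratio,
            "p_value": self.p_value,
            "thresholds": list(self.thresholds) if self.thresholds else None,
        }


def fisher_odds_ratio(
    table: Sequence[Sequence[int]],
    thresholds: tuple[float, float] | None = None,
    haldane: bool = False,
) -> OddsRatioResult:
    """Sample odds ratio (n11*n22)/(n12*n21) with two-sided Fisher exact p.

    A zero denominator cell with positive numerator gives +inf; `haldane`
    adds 0.5 to every cell for the odds-ratio estimate only.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    if t.sum() == 0:
        raise ValueError("all-zero table")
    if haldane:
        th = t + 0.5
        odds = float(th[0, 0] * th[1, 1] / (th[0, 1] * th[1, 0]))
    else:
        num = float(t[0, 0] * t[1, 1])
        den = float(t[0, 1] * t[1, 0])
        if den == 0:
            odds = float("inf") if num > 0 else float("nan")
        else:
            odds = num / den
    return OddsRatioResult(t, odds, fisher_exact_p(t), thresholds)


def quadrant_odds_ratio(
    signal_x: Sequence[float],
    signal_y: Sequence[float],
    thresh_x: float | None = None,
    thresh_y: float | None = None,
    haldane: bool = False,
) -> OddsRatioResult:
    """Quadrant table + Fisher odds ratio; thresholds default to each
    signal's median (recorded in the result)."""
    tx = float(np.median(signal_x)) if thresh_x is None else thresh_x
    ty = float(np.median(signal_y)) if thresh_y is None else thresh_y
    table = quadrant_table(signal_x, signal_y, tx, ty)
    return fisher_odds_ratio(table, thresholds=(tx, ty), haldane=haldane)


@dataclass(frozen=True)
class GroupCoverage:
    group: int
    n_regions: int
    n_covered: int

    @property
    def fraction(self) -> float:
        return self.n_covered / self.n_regions if self.n_regions else float("nan")


def group_coverage(
    records: Sequence[PreferenceRecord], factor_peaks: Sequence
) -> dict[int, GroupCoverage]:
    """Per preference group, the fraction of regions overlapping (>= 1 bp)
    any factor peak."""
    idx = IntervalIndex([as_interval(p) for p in factor_peaks])
    out: dict[int, GroupCoverage] = {}
    for g in range(1, 7):
        members = [r for r in records if r.group == g]
        covered = sum(1 for r in members if idx.overlaps(r.region))
        out[g] = GroupCoverage(g, len(members), covered)
    return out


@dataclass(frozen=True)
class PeakResponse:
    """Treatment response of a peak set: fractions over control peaks."""

    n_control: int
    lost: float
    decreased: float
    increased: float
    unchanged: float

    def summary(self) -> dict:
        return {
            "n_control": self.n_control,
            "lost": self.lost,
            "decreased": self.decreased,
            "increased": self.increased,
            "unchanged": self.unchanged,
        }


def peak_response(
    peaks_control: Sequence,
    peaks_treated: Sequence,
    signal_control: SignalTrack | None = None,
    signal_treated: SignalTrack | None = None,
    fc_thresh: float = 0.5,
    pseudocount: float = 1.0,
) -> PeakResponse:
    """Classify each control peak as lost / decreased / increased / unchanged.

    Lost = no treated peak overlaps it (>= 1 bp).  Retained peaks are split
    by the log2 ratio of treated vs control region density (pseudocount 1):
    decreased below -fc_thresh, increased above +fc_thresh, else unchanged.
    Without signal tracks, retained peaks are all counted as unchanged.
    """
    controls = [as_interval(p) for p in peaks_control]
    if not controls:
        return PeakResponse(0, float("nan"), float("nan"), float("nan"), float("nan"))
    idx = IntervalIndex([as_interval(p) for p in peaks_treated])
    n = len(controls)
    n_lost = n_dec = n_inc = n_same = 0
    for iv in controls:
        if not idx.overlaps(iv):
            n_lost += 1
            continue
        if signal_control is None or signal_treated is None:
            n_same += 1
            continue
        dc = region_signal(signal_control, iv).density
        dt = region_signal(signal_treated, iv).density
        lfc = math.log2((dt + pseudocount) / (dc + pseudocount))
        if lfc < -fc_thresh:
            n_dec += 1
        elif lfc > fc_thresh:
            n_inc += 1
        else:
            n_same += 1
    return PeakResponse(n, n_lost / n, n_dec / n, n_inc / n, n_same / n)
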