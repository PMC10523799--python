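"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates the statistical structure of a two-mark histone
acetylation study in a treated-vs-control design: two correlated
acetylation marks whose per-region log2 ratio is planted on a six-group
preference grid, clusters of high-signal peaks that must stitch into
super-enhancers, a co-binding factor (BRD4-like) with group-graded binding
probability that is largely depleted by treatment, and gene-level
expression counts whose treatment response is concentrated on the most
mark-A-preferred group and whose baseline couples to promoter signal.

Coverage tracks are rectangular pulses over the peak intervals (zero in
between), which keeps every region-signal ground truth analytic.  All
randomness flows from one integer seed; coordinates are integers and signal
values are rounded to 6 decimals, so outputs are byte-identical across runs
and platforms.
"""
from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    GenomicInterval,
    Peak,
    SignalTrack,
    TSSAnnotation,
    TSSRecord,
    write_counts,
)

GROUP_CENTERS = (-2.5, -1.5, -0.5, 0.5, 1.5, 2.5)


@dataclass(frozen=True)
class SimConfig:
    """All planted parameters of one simulation."""

    seed: int = 0
    chrom_lengths: tuple[tuple[str, int], ...] = (
        ("chrS1", 15_000_000),
        ("chrS2", 15_000_000),
    )
    n_genes: int = 300
    n_typical_peaks: int = 500
    n_se_clusters: int = 5
    peaks_per_cluster: int = 8
    cluster_span: int = 8000  # < stitch distance, so a cluster stitches whole
    peak_width: tuple[int, int] = (400, 800)
    gap_range: tuple[int, int] = (25_000, 60_000)  # > stitch distance
    signal_log_mean: float = math.log(150.0)  # per-kb density, log-normal
    signal_log_sd: float = 0.6
    min_base_density: float = 8.0
    se_multiplier: float = 50.0
    group_proportions: tuple[float, ...] = (0.05, 0.15, 0.30, 0.30, 0.15, 0.05)
    jitter_sd: float = 0.25  # within-group log2FC jitter
    factor_bind_prob: tuple[float, ...] = (0.13, 0.15, 0.18, 0.20, 0.23, 0.26)
    factor_loss_prob: float = 0.95  # treatment depletion of factor peaks
    factor_log_density: float = math.log(100.0)
    mark_a_treatment_log2fc: tuple[float, ...] = (0.0,) * 6
    mark_b_treatment_log2fc: tuple[float, ...] = (0.0,) * 6
    expression_baseline_log2: float = 8.0  # log2 expected counts per gene
    dispersion: float = 0.1  # NB: var = mu + dispersion * mu^2
    n_replicates: int = 2
    treatment_effect: tuple[float, ...] = (0.0, 0.0, 0.0, -0.2, -0.5, -1.0)
    effect_sd: float = 0.3
    coupling: float = 0.2  # log2-mean shift per SD of promoter signal

    def validate(self) -> None:
        if len(self.group_proportions) != 6 or not math.isclose(
            sum(self.group_proportions), 1.0, abs_tol=1e-9
        ):
            raise ValueError("group_proportions must be 6 values summing to 1")
        for p in (*self.group_proportions, *self.factor_bind_prob, self.factor_loss_prob):
            if not 0 <= p <= 1:
                raise ValueError(f"probability out of [0, 1]: {p}")
        if any(l <= 0 for _, l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.n_genes > self.n_typical_peaks:
            raise ValueError("n_genes cannot exceed n_typical_peaks")
        if self.cluster_span >= self.gap_range[0]:
            raise ValueError("cluster_span must be smaller than the minimum gap")


def _allocate_groups(n: int, proportions: Sequence[float], rng) -> np.ndarray:
    """Deterministic largest-remainder allocation, then a seeded shuffle."""
    raw = np.asarray(proportions) * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    for g in order[:remainder]:
        counts[g] += 1
    labels = np.repeat(np.arange(1, 7), counts)
    return rng.permutation(labels)


@dataclass
class SimData:
    """In-memory simulation output plus the ground-truth record."""

    config: SimConfig
    chrom_sizes: dict[str, int]
    peaks_a: list[Peak]
    peaks_b: list[Peak]
    factor_peaks: list[Peak]
    factor_peaks_treated: list[Peak]
    tracks: dict[tuple[str, str], SignalTrack]  # (mark, condition) -> track
    tss: TSSAnnotation
    counts: pd.DataFrame
    samples: dict[str, list[str]]
    truth: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        def np_path(key: str, peaks: list[Peak]) -> None:
            p = outdir / f"{key}.narrowPeak"
            with open(p, "w") as fh:
                for pk in peaks:
                    offset = pk.summit - pk.start if pk.summit is not None else -1
                    fh.write(
                        f"{pk.chrom}\t{pk.start}\t{pk.end}\t{pk.name}\t0\t.\t"
                        f"{round(pk.signal, 6):g}\t-1\t-1\t{offset}\n"
                    )
            paths[key] = p

        np_path("mark_a_peaks", self.peaks_a)
        np_path("mark_b_peaks", self.peaks_b)
        np_path("factor_peaks", self.factor_peaks)
        np_path("factor_treated_peaks", self.factor_peaks_treated)
        for (mark, condition), track in sorted(self.tracks.items()):
            key = f"{mark}_{condition}"
            p = outdir / f"{key}.bedGraph"
            track.to_bedgraph(p)
            paths[key] = p
        paths["tss"] = outdir / "tss.tsv"
        self.tss.to_tsv(paths["tss"])
        paths["counts"] = outdir / "counts.tsv"
        write_counts(self.counts, paths["counts"])
        paths["chrom_sizes"] = outdir / "chrom_sizes.tsv"
        with open(paths["chrom_sizes"], "w") as fh:
            for chrom, size in self.chrom_sizes.items():
                fh.write(f"{chrom}\t{size}\n")
        paths["truth"] = outdir / "truth.json"
        with open(paths["truth"], "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)
        return paths


def simulate(config: SimConfig) -> SimData:
    config.validate()
    rng = np.random.default_rng(config.seed)
    chrom_sizes = dict(config.chrom_lengths)
    chroms = list(chrom_sizes)

    # --- place peak units (isolated typical peaks + clusters) -------------
    n_units = config.n_typical_peaks + config.n_se_clusters
    unit_kind = ["typical"] * config.n_typical_peaks + [
        "cluster"
    ] * config.n_se_clusters
    unit_order = rng.permutation(n_units)
    cursors = {c: 100_000 for c in chroms}
    margin = 100_000
    peak_rows: list[dict] = []  # one per peak, in placement order
    cluster_spans: dict[int, list[int]] = {}
    cluster_counter = 0
    for ui, u in enumerate(unit_order):
        chrom = chroms[ui % len(chroms)]
        gap = int(rng.integers(*config.gap_range))
        pos = cursors[chrom] + gap
        if unit_kind[u] == "typical":
            width = int(rng.integers(config.peak_width[0], config.peak_width[1] + 1))
            peak_rows.append(
                {"chrom": chrom, "start": pos, "end": pos + width, "cluster": None}
            )
            cursors[chrom] = pos + width
        else:
            cid = cluster_counter
            cluster_counter += 1
            starts = np.sort(
                rng.choice(
                    np.arange(0, config.cluster_span, 50), config.peaks_per_cluster,
                    replace=False,
                )
            )
            prev_end = -1
            cstart, cend = None, None
            for s in starts:
                width = int(
                    rng.integers(config.peak_width[0], config.peak_width[1] + 1)
                )
                start = pos + int(s)
                if start <= prev_end:
                    start = prev_end + 10
                end = start + width
                prev_end = end
                peak_rows.append(
                    {"chrom": chrom, "start": start, "end": end, "cluster": cid}
                )
                cstart = start if cstart is None else cstart
                cend = end
            cluster_spans[cid] = [chrom, cstart, cend]
            cursors[chrom] = cend
        if cursors[chrom] > chrom_sizes[chrom] - margin:
            raise ValueError(
                f"infeasible placement: ran past {chrom} "
                f"({cursors[chrom]} > {chrom_sizes[chrom] - margin}); "
                "increase chromosome lengths or reduce peak counts"
            )

    n_peaks = len(peak_rows)
    groups = _allocate_groups(n_peaks, config.group_proportions, rng)
    jitter = rng.normal(0.0, config.jitter_sd, n_peaks) if config.jitter_sd > 0 else np.zeros(n_peaks)
    target_lfc = np.clip(
        np.array([GROUP_CENTERS[g - 1] for g in groups]) + jitter, -6.0, 6.0
    )
    base = np.maximum(
        rng.lognormal(config.signal_log_mean, config.signal_log_sd, n_peaks),
        config.min_base_density,
    )
    is_cluster = np.array([r["cluster"] is not None for r in peak_rows])
    base = np.where(is_cluster, base * config.se_multiplier, base)
    # geometric split around the base keeps both densities positive and the
    # log2 ratio of pseudocounted densities exactly equal to the target
    dens_a = np.round((base + 1.0) * np.exp2(target_lfc / 2.0) - 1.0, 6)
    dens_b = np.round((base + 1.0) * np.exp2(-target_lfc / 2.0) - 1.0, 6)

    bound = rng.random(n_peaks) < np.array(
        [config.factor_bind_prob[g - 1] for g in groups]
    )
    retained = bound & (rng.random(n_peaks) >= config.factor_loss_prob)
    factor_density = np.round(
        np.maximum(rng.lognormal(config.factor_log_density, 0.5, n_peaks), 1.0), 6
    )

    peaks_a: list[Peak] = []
    peaks_b: list[Peak] = []
    factor_peaks: list[Peak] = []
    factor_treated: list[Peak] = []
    for i, row in enumerate(peak_rows):
        iv = GenomicInterval(row["chrom"], row["start"], row["end"])
        summit = iv.midpoint
        name = f"pk{i:05d}"
        peaks_a.append(Peak(iv, summit, float(dens_a[i]), None, name))
        peaks_b.append(Peak(iv, summit, float(dens_b[i]), None, name))
        if bound[i]:
            fp = Peak(iv, summit, float(factor_density[i]), None, f"f_{name}")
            factor_peaks.append(fp)
            if retained[i]:
                factor_treated.append(fp)

    def track_from(densities: np.ndarray, mask: np.ndarray | None = None) -> SignalTrack:
        runs = []
        for i, row in enumerate(peak_rows):
            if mask is not None and not mask[i]:
                continue
            h = round(float(densities[i]) / 1000.0, 6)
            if h > 0:
                runs.append((row["chrom"], row["start"], row["end"], h))
        return SignalTrack.from_runs(runs)

    shift_a = np.exp2([config.mark_a_treatment_log2fc[g - 1] for g in groups])
    shift_b = np.exp2([config.mark_b_treatment_log2fc[g - 1] for g in groups])
    tracks = {
        ("mark_a", "control"): track_from(dens_a),
        ("mark_a", "treated"): track_from(np.round(dens_a * shift_a, 6)),
        ("mark_b", "control"): track_from(dens_b),
        ("mark_b", "treated"): track_from(np.round(dens_b * shift_b, 6)),
        ("factor", "control"): track_from(factor_density, bound),
        ("factor", "treated"): track_from(factor_density, retained),
    }

    # --- genes: TSS near the summit of a subset of typical peaks ----------
    typical_idx = np.flatnonzero(~is_cluster)
    promoter_peak_idx = np.sort(
        rng.choice(typical_idx, config.n_genes, replace=False)
    )
    tss_records = []
    gene_rows = []
    z_source = np.log2(dens_a[promoter_peak_idx] + 1.0)
    z = (z_source - z_source.mean()) / (z_source.std() if z_source.std() > 0 else 1.0)
    true_lfc = np.array(
        [config.treatment_effect[groups[i] - 1] for i in promoter_peak_idx]
    ) + (rng.normal(0.0, config.effect_sd, config.n_genes) if config.effect_sd > 0 else 0.0)
    for k, i in enumerate(promoter_peak_idx):
        row = peak_rows[i]
        gene_id = f"g{k:04d}"
        summit = (row["start"] + row["end"]) // 2
        offset = int(rng.integers(-300, 301))
        strand = "+" if rng.random() < 0.5 else "-"
        tss_records.append(
            TSSRecord(gene_id, row["chrom"], max(0, summit + offset), strand)
        )
        mu = config.expression_baseline_log2 + config.coupling * z[k]
        gene_rows.append(
            {
                "gene_id": gene_id,
                "peak": f"pk{i:05d}",
                "group": int(groups[i]),
                "true_log2fc": round(float(true_lfc[k]), 6),
                "log2_mean": round(float(mu), 6),
            }
        )
    tss = TSSAnnotation(tss_records)

    # --- negative-binomial counts -----------------------------------------
    nrep = config.n_replicates
    samples = {
        "control": [f"ctrl_{j + 1}" for j in range(nrep)],
        "treated": [f"trt_{j + 1}" for j in range(nrep)],
    }
    mu_ctrl = np.exp2([g["log2_mean"] for g in gene_rows])
    mu_trt = mu_ctrl * np.exp2([g["true_log2fc"] for g in gene_rows])

    def nb_draws(mu: np.ndarray, size: int) -> np.ndarray:
        if config.dispersion <= 0:
            return rng.poisson(mu[:, None], (len(mu), size))
        r = 1.0 / config.dispersion
        p = r / (r + mu)
        return rng.negative_binomial(r, p[:, None], (len(mu), size))

    counts = pd.DataFrame(
        np.hstack([nb_draws(mu_ctrl, nrep), nb_draws(mu_trt, nrep)]),
        index=pd.Index([g["gene_id"] for g in gene_rows], name="gene_id"),
        columns=samples["control"] + samples["treated"],
    )

    truth = {
        "config": dataclasses.asdict(config),
        "peaks": [
            {
                "name": f"pk{i:05d}",
                "chrom": row["chrom"],
                "start": row["start"],
                "end": row["end"],
                "group": int(groups[i]),
                "log2fc": round(float(target_lfc[i]), 6),
                "density_a": float(dens_a[i]),
                "density_b": float(dens_b[i]),
                "cluster": row["cluster"],
                "factor_bound": bool(bound[i]),
                "factor_retained": bool(retained[i]),
            }
            for i, row in enumerate(peak_rows)
        ],
        "clusters": [
            {"id": cid, "chrom": c, "start": s, "end": e}
            for cid, (c, s, e) in sorted(cluster_spans.items())
        ],
        "genes": gene_rows,
        "samples": samples,
    }
    return SimData(
        config,
        chrom_sizes,
        peaks_a,
        peaks_b,
        factor_peaks,
        factor_treated,
        tracks,
        tss,
        counts,
        samples,
        truth,
    )


def pipeline_config(
    paths: Mapping[str, Path],
    outdir: str | Path,
    control_samples: Sequence[str] = ("ctrl_1", "ctrl_2"),
    treated_samples: Sequence[str] = ("trt_1", "trt_2"),
) -> dict:
    """Assemble a full-pipeline run configuration from `SimData.write` paths."""
    return {
        "inputs": {
            "mark_a": {
                "peaks": str(paths["mark_a_peaks"]),
                "signal": str(paths["mark_a_control"]),
                "signal_treated": str(paths["mark_a_treated"]),
            },
            "mark_b": {
                "peaks": str(paths["mark_b_peaks"]),
                "signal": str(paths["mark_b_control"]),
                "signal_treated": str(paths["mark_b_treated"]),
            },
            "factor": {
                "peaks": str(paths["factor_peaks"]),
                "peaks_treated": str(paths["factor_treated_peaks"]),
                "signal": str(paths["factor_control"]),
                "signal_treated": str(paths["factor_treated"]),
            },
            "tss": str(paths["tss"]),
            "counts": str(paths["counts"]),
            "control_samples": list(control_samples),
            "treated_samples": list(treated_samples),
        },
        "outdir": str(outdir),
    }


@dataclass(frozen=True)
class QuadrantSim:
    """Paired continuous signals with a planted quadrant odds ratio."""

    x: np.ndarray
    y: np.ndarray
    thresh_x: float
    thresh_y: float
    table: np.ndarray  # planted multinomial counts
    log_odds_ratio: float


def simulate_quadrant(
    n: int,
    log_odds_ratio: float,
    seed: int,
    p_x: float = 0.5,
    p_y: float = 0.5,
) -> QuadrantSim:
    """Paired signals whose strong/weak dichotomy at the returned thresholds
    has the planted odds ratio (in expectation).

    Cell probabilities are solved from the margins and the OR; weak values
    are drawn on [0, 1) and strong values on [2, 3), with thresholds at 1.5,
    so the quadrant table recovers the planted multinomial counts exactly.
    """
    orr = math.exp(log_odds_ratio)
    if math.isclose(orr, 1.0):
        p11 = p_x * p_y
    else:
        a = orr - 1.0
        b = -((orr - 1.0) * (p_x + p_y) + 1.0)
        c = orr * p_x * p_y
        disc = math.sqrt(b * b - 4 * a * c)
        roots = [(-b - disc) / (2 * a), (-b + disc) / (2 * a)]
        lo, hi = max(0.0, p_x + p_y - 1.0), min(p_x, p_y)
        p11 = next(r for r in roots if lo <= r <= hi)
    probs = [p11, p_x - p11, p_y - p11, 1.0 - p_x - p_y + p11]
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, probs)
    table = np.array([[counts[0], counts[1]], [counts[2], counts[3]]])
    sx = np.concatenate(
        [np.ones(counts[0]), np.ones(counts[1]), np.zeros(counts[2]), np.zeros(counts[3])]
    )
    sy = np.concatenate(
        [np.ones(counts[0]), np.zeros(counts[1]), np.ones(counts[2]), np.zeros(counts[3])]
    )
    x = np.where(sx > 0, rng.uniform(2, 3, n), rng.uniform(0, 1, n))
    y = np.where(sy > 0, rng.uniform(2, 3, n), rng.uniform(0, 1, n))
    perm = rng.permutation(n)
    return QuadrantSim(x[perm], y[perm], 1.5, 1.5, table, log_odds_ratio)


def interval_jaccard(a: GenomicInterval, b: GenomicInterval) -> float:
    if a.chrom != b.chrom:
        return 0.0
    inter = max(0, min(a.end, b.end) - max(a.start, b.start))
    union = (a.end - a.start) + (b.end - b.start) - inter
    return inter / union if union else 0.0


def truth_compare(
    truth: dict,
    se_result=None,
    records=None,
    or_result=None,
    planted_log_or: float | None = None,
    shift=None,
    spearman_estimate: float | None = None,
) -> dict:
    """Recovery report comparing pipeline outputs against planted truth.

    Every section is present in the report; sections whose inputs were not
    supplied are None.  Records are matched to truth peaks by exact
    coordinates; unmatched records raise.
    """
    report: dict = {
        "group_recovery": None,
        "se_recovery": None,
        "odds_ratio_recovery": None,
        "expression_shift": None,
        "spearman_estimate": spearman_estimate,
    }
    if records is not None:
        true_group = {
            (p["chrom"], p["start"], p["end"]): p["group"] for p in truth["peaks"]
        }
        confusion = np.zeros((6, 6), dtype=int)
        for r in records:
            key = (r.region.chrom, r.region.start, r.region.end)
            if key not in true_group:
                raise ValueError(f"record region {key} not found in truth")
            confusion[true_group[key] - 1, r.group - 1] += 1
        total = confusion.sum()
        agreement = float(np.trace(confusion) / total) if total else float("nan")
        report["group_recovery"] = {
            "confusion": confusion.tolist(),
            "agreement": agreement,
            "n": int(total),
        }
    if se_result is not None:
        se_ivs = [r.interval for r in se_result.superenhancers()]
        per_cluster = []
        for cl in truth["clusters"]:
            span = GenomicInterval(cl["chrom"], cl["start"], cl["end"])
            best = max(
                (interval_jaccard(span, iv) for iv in se_ivs), default=0.0
            )
            per_cluster.append(best)
        report["se_recovery"] = {
            "n_clusters": len(per_cluster),
            "jaccard": per_cluster,
            "jaccard_min": min(per_cluster, default=float("nan")),
            "jaccard_mean": float(np.mean(per_cluster)) if per_cluster else float("nan"),
            "n_superenhancers": len(se_ivs),
        }
    if or_result is not None:
        t = np.asarray(or_result.table, dtype=float)
        log_est = (
            math.log(or_result.odds_ratio)
            if 0 < or_result.odds_ratio < math.inf
            else float("nan")
        )
        se = float(np.sqrt(np.sum(1.0 / np.maximum(t, 1e-300)))) if (t > 0).all() else float("nan")
        entry = {"log_or_estimate": log_est, "analytic_se": se}
        if planted_log_or is not None:
            entry["planted_log_or"] = planted_log_or
            entry["z"] = (
                (log_est - planted_log_or) / se
                if not (math.isnan(log_est) or math.isnan(se))
                else float("nan")
            )
        report["odds_ratio_recovery"] = entry
    if shift is not None:
        effects = truth["config"]["treatment_effect"]
        entry = shift.summary()
        if shift.group_x is not None and shift.group_y is not None:
            entry["planted_difference"] = (
                effects[shift.group_x - 1] - effects[shift.group_y - 1]
            )
        report["expression_shift"] = entry
    return report
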