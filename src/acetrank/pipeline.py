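"""Config-driven end-to-end driver: marks -> SEs -> preference groups ->
colocalization -> gene association -> expression integration.

The run configuration is a plain mapping (usually loaded from YAML) with an
``inputs`` section (file paths), a ``params`` section (all tunables, each
with a default) and an ``outdir``.  Outputs are deterministic: identical
inputs and parameters give byte-identical TSV/JSON files (floats are
serialized at fixed precision).
"""
from __future__ import annotations

import hashlib
import json
import logging
import math
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .colocalization import group_coverage, peak_response, quadrant_odds_ratio
from .expression_stats import de_table, group_expression_shift, rank_correlation, cpm
from .gene_assoc import associate, associations_to_frame, build_domains, nearest_tss
from .io_formats import (
    Peak,
    SignalTrack,
    TSSAnnotation,
    read_bed,
    read_bedgraph,
    read_counts,
    read_narrowpeak,
    write_bed,
)
from .preference import (
    PreferenceRecord,
    compare_sets,
    preference_table,
    records_to_frame,
    region_universe,
)
from .se_caller import call_superenhancers
from .signal_quant import region_signal

log = logging.getLogger("acetrank")

DEFAULT_PARAMS: dict[str, Any] = {
    "stitch_distance": 12500,
    "tss_exclusion": False,
    "tss_window": 2500,
    "position_window": 1000,
    "pseudocount": 1.0,
    "de_pseudocount": 0.5,
    "fdr_thresh": 0.05,
    "lfc_thresh": 0.5,
    "min_overlap_bp": 1,
    "upstream": 5000,
    "downstream": 1000,
    "max_extension": 1_000_000,
    "shift_groups": [6, 1],
    # [thresh_x, thresh_y] for the quadrant analysis; null -> per-signal median
    "quadrant_thresholds": None,
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def validate_config(config: Mapping) -> list[str]:
    """Return a list of problems; empty iff the configuration is runnable."""
    problems: list[str] = []
    inputs = config.get("inputs")
    if not isinstance(inputs, Mapping):
        return ["inputs: missing or not a mapping"]
    for mark in ("mark_a", "mark_b"):
        section = inputs.get(mark)
        if not isinstance(section, Mapping):
            problems.append(f"inputs.{mark}: missing")
            continue
        for key in ("peaks", "signal"):
            if key not in section:
                problems.append(f"inputs.{mark}.{key}: missing")
            elif not Path(section[key]).exists():
                problems.append(f"inputs.{mark}.{key}: file not found: {section[key]}")
    for key in ("tss", "counts", "input_control"):
        if key in inputs and not Path(inputs[key]).exists():
            problems.append(f"inputs.{key}: file not found: {inputs[key]}")
    factor = inputs.get("factor")
    if factor is not None:
        for key, path in factor.items():
            if key.startswith("peaks") or key.startswith("signal"):
                if not Path(path).exists():
                    problems.append(f"inputs.factor.{key}: file not found: {path}")
    if "counts" in inputs:
        for key in ("control_samples", "treated_samples"):
            if not inputs.get(key):
                problems.append(f"inputs.{key}: required with counts")
    params = {**DEFAULT_PARAMS, **config.get("params", {})}
    for key in (
        "stitch_distance",
        "tss_window",
        "position_window",
        "min_overlap_bp",
        "upstream",
        "downstream",
        "max_extension",
    ):
        if not isinstance(params[key], int) or params[key] < 0:
            problems.append(f"params.{key}: must be a non-negative integer")
    for key in ("pseudocount", "de_pseudocount", "fdr_thresh", "lfc_thresh"):
        if not isinstance(params[key], (int, float)) or params[key] < 0:
            problems.append(f"params.{key}: must be a non-negative number")
    sg = params["shift_groups"]
    if (
        not isinstance(sg, (list, tuple))
        or len(sg) != 2
        or not all(isinstance(g, int) and 1 <= g <= 6 for g in sg)
    ):
        problems.append("params.shift_groups: must be two group numbers in 1..6")
    if "outdir" not in config:
        problems.append("outdir: missing")
    return problems


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, float):
        if math.isnan(obj):
            return None
        if math.isinf(obj):
            return "inf" if obj > 0 else "-inf"
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_peaks(path: str | Path) -> list[Peak]:
    path = Path(path)
    if path.suffix.lower() == ".bed":
        return [Peak(iv) for iv in read_bed(path)]
    return read_narrowpeak(path)


def run_pipeline(config: Mapping) -> dict:
    """Execute all stages; write intermediates and report.json to outdir.

    Any stage failure aborts with the stage name; partial outputs are kept
    alongside a FAILED marker naming the stage.
    """
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid configuration: " + "; ".join(problems))
    inputs = config["inputs"]
    params = {**DEFAULT_PARAMS, **config.get("params", {})}
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)

    report: dict = {
        "provenance": {
            "tool": "acetrank",
            "version": __version__,
            "params": params,
            "input_checksums": {},
        }
    }
    current_stage = "load_inputs"
    try:
        # ---------------- load ----------------
        log.info("stage load_inputs")
        peaks_a = _read_peaks(inputs["mark_a"]["peaks"])
        peaks_b = _read_peaks(inputs["mark_b"]["peaks"])
        track_a = read_bedgraph(inputs["mark_a"]["signal"])
        track_b = read_bedgraph(inputs["mark_b"]["signal"])
        input_track = (
            read_bedgraph(inputs["input_control"])
            if inputs.get("input_control")
            else None
        )
        tss = TSSAnnotation.from_tsv(inputs["tss"]) if inputs.get("tss") else None
        counts = read_counts(inputs["counts"]) if inputs.get("counts") else None
        factor_cfg = inputs.get("factor") or {}
        factor_peaks = (
            _read_peaks(factor_cfg["peaks"]) if factor_cfg.get("peaks") else None
        )
        factor_peaks_treated = (
            _read_peaks(factor_cfg["peaks_treated"])
            if factor_cfg.get("peaks_treated")
            else None
        )
        factor_track = (
            read_bedgraph(factor_cfg["signal"]) if factor_cfg.get("signal") else None
        )
        for label, path in _input_paths(inputs):
            report["provenance"]["input_checksums"][label] = _sha256(path)
        report["peaks"] = {
            "mark_a": len(peaks_a),
            "mark_b": len(peaks_b),
            "factor": len(factor_peaks) if factor_peaks is not None else None,
        }

        # ---------------- SE calling per mark ----------------
        current_stage = "se_call"
        log.info("stage se_call")
        se_results = {}
        for mark, peaks, track in (
            ("mark_a", peaks_a, track_a),
            ("mark_b", peaks_b, track_b),
        ):
            res = call_superenhancers(
                peaks,
                track,
                input_track,
                stitch_distance=params["stitch_distance"],
                tss_exclusion=tss if params["tss_exclusion"] else None,
                tss_window=params["tss_window"],
            )
            se_results[mark] = res
            frame = res.to_frame()
            frame.to_csv(
                outdir / f"se_{mark}_regions.tsv",
                sep="\t",
                index=False,
                float_format="%.6g",
            )
            ses = res.superenhancers()
            write_bed(
                [r.interval for r in ses],
                outdir / f"se_{mark}.bed",
                extra_columns=[[r.rank, round(r.signal, 6)] for r in ses],
            )
            report[f"se_{mark}"] = res.summary()

        # ---------------- SE set comparison ----------------
        current_stage = "se_compare"
        log.info("stage se_compare")
        comparison = compare_sets(
            [r.interval for r in se_results["mark_a"].superenhancers()],
            [r.interval for r in se_results["mark_b"].superenhancers()],
            min_overlap_bp=params["min_overlap_bp"],
        )
        report["se_comparison"] = comparison.summary()

        # ---------------- preference classification ----------------
        current_stage = "preference"
        log.info("stage preference")
        universe = region_universe(peaks_a, peaks_b)
        records = preference_table(
            universe,
            track_a,
            track_b,
            tss=tss,
            window=params["position_window"],
            pseudocount=params["pseudocount"],
            input_track=input_track,
        )
        records = _attach_genes(records, tss, params)
        records_to_frame(records).to_csv(
            outdir / "preference.tsv", sep="\t", index=False, float_format="%.6g"
        )
        group_sizes = {g: sum(1 for r in records if r.group == g) for g in range(1, 7)}
        report["preference"] = {
            "n_regions": len(records),
            "group_sizes": group_sizes,
            "n_promoters": sum(1 for r in records if r.position_class == "promoter"),
            "n_enhancers": sum(1 for r in records if r.position_class == "enhancer"),
        }

        # ---------------- colocalization ----------------
        current_stage = "colocalization"
        log.info("stage colocalization")
        coloc: dict = {"quadrant": None, "coverage": None, "factor_response": None}
        if factor_peaks is not None:
            if factor_track is not None:
                fx = [
                    region_signal(factor_track, r.region).density for r in records
                ]
                qt = params["quadrant_thresholds"]
                orr = quadrant_odds_ratio(
                    fx,
                    [r.signal_a for r in records],
                    thresh_x=qt[0] if qt else None,
                    thresh_y=qt[1] if qt else None,
                )
                coloc["quadrant"] = orr.summary()
            cov = group_coverage(records, factor_peaks)
            coloc["coverage"] = {
                g: {
                    "n_regions": c.n_regions,
                    "n_covered": c.n_covered,
                    "fraction": c.fraction,
                }
                for g, c in cov.items()
            }
            if factor_peaks_treated is not None:
                factor_track_treated = (
                    read_bedgraph(factor_cfg["signal_treated"])
                    if factor_cfg.get("signal_treated")
                    else None
                )
                resp = peak_response(
                    factor_peaks,
                    factor_peaks_treated,
                    factor_track,
                    factor_track_treated,
                    fc_thresh=params["lfc_thresh"],
                    pseudocount=params["pseudocount"],
                )
                coloc["factor_response"] = resp.summary()
        report["colocalization"] = coloc
        with open(outdir / "colocalization.json", "w") as fh:
            json.dump(_round_floats(coloc), fh, indent=1, sort_keys=True)

        # ---------------- gene association of SEs ----------------
        current_stage = "gene_association"
        log.info("stage gene_association")
        if tss is not None:
            domains = build_domains(
                tss,
                upstream=params["upstream"],
                downstream=params["downstream"],
                max_extension=params["max_extension"],
            )
            assoc: dict = {}
            for mark in ("mark_a", "mark_b"):
                ses = se_results[mark].superenhancers()
                links = associate([r.interval for r in ses], domains)
                associations_to_frame(links).to_csv(
                    outdir / f"se_{mark}_genes.tsv", sep="\t", index=False
                )
                genes = sorted({g for l in links for g, _ in l.genes})
                assoc[mark] = {"n_se": len(ses), "n_genes": len(genes)}
            report["gene_association"] = assoc
        else:
            report["gene_association"] = None

        # ---------------- expression ----------------
        current_stage = "expression"
        log.info("stage expression")
        expression: dict = {
            "de_classes": None,
            "group_shift": None,
            "signal_expression_spearman": None,
        }
        if counts is not None:
            de = de_table(
                counts,
                inputs["control_samples"],
                inputs["treated_samples"],
                pseudocount=params["de_pseudocount"],
                fdr_thresh=params["fdr_thresh"],
                lfc_thresh=params["lfc_thresh"],
            )
            de.to_csv(outdir / "de.tsv", sep="\t", float_format="%.6g")
            expression["de_classes"] = de["de_class"].value_counts().to_dict()
            promoter_records = [
                r for r in records if r.position_class == "promoter" and r.genes
            ]
            gx, gy = params["shift_groups"]
            try:
                shift = group_expression_shift(promoter_records, de, gx, gy)
                expression["group_shift"] = shift.summary()
            except ValueError as exc:
                log.warning("group shift skipped: %s", exc)
            pairs = [
                (math.log2(r.signal_a + 1.0), g)
                for r in promoter_records
                for g in r.genes[:1]
                if g in counts.index
            ]
            if len(pairs) >= 3:
                mean_ctrl = np.log2(
                    cpm(counts)[list(inputs["control_samples"])].mean(axis=1) + 1.0
                )
                expression["signal_expression_spearman"] = rank_correlation(
                    [s for s, _ in pairs], [mean_ctrl[g] for _, g in pairs]
                )
        report["expression"] = expression
    except Exception as exc:  # noqa: BLE001 - abort with stage context
        (outdir / "FAILED").write_text(f"{current_stage}: {exc}\n")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(current_stage, exc) from exc

    report = _round_floats(report)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return report


def _input_paths(inputs: Mapping):
    for mark in ("mark_a", "mark_b"):
        for key, path in inputs[mark].items():
            yield f"{mark}.{key}", path
    for key in ("tss", "counts", "input_control"):
        if inputs.get(key):
            yield key, inputs[key]
    for key, path in (inputs.get("factor") or {}).items():
        if key.startswith(("peaks", "signal")):
            yield f"factor.{key}", path


def _attach_genes(
    records: list[PreferenceRecord], tss: TSSAnnotation | None, params: Mapping
) -> list[PreferenceRecord]:
    """Promoter regions get their nearest gene; enhancer regions get every
    gene whose basal-plus-extension domain they overlap."""
    if tss is None:
        return records
    import dataclasses

    nearest = nearest_tss([r.region for r in records], tss)
    domains = build_domains(
        tss,
        upstream=params["upstream"],
        downstream=params["downstream"],
        max_extension=params["max_extension"],
    )
    enhancer_idx = [i for i, r in enumerate(records) if r.position_class != "promoter"]
    links = associate([records[i].region for i in enhancer_idx], domains)
    by_idx = dict(zip(enhancer_idx, links))
    out = []
    for i, r in enumerate(records):
        if r.position_class == "promoter":
            genes = (nearest[i][0],) if nearest[i] is not None else ()
        else:
            genes = tuple(g for g, _ in by_idx[i].genes) if i in by_idx else ()
        out.append(dataclasses.replace(r, genes=genes))
    return out
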