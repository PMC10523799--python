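# acetrank

Super-enhancer calling by an arbitrary histone-acetylation mark, and
differential mark-preference analysis of regulatory regions.

## The problem

Super-enhancers (SEs) are conventionally identified by ranking stitched
enhancer regions on H3K27ac ChIP-seq signal and cutting the rank–signal
curve geometrically. Other acetylation marks — in particular H4K5acK8ac,
the di-acetylated histone H4 mark read directly by BET-family bromodomains
such as BRD4 — can rank a partly different set of SEs and mark regulatory
regions whose activity responds differently to BET inhibition (e.g. JQ1).

`acetrank` implements that analysis as a reusable, tested pipeline for
anyone comparing two acetylation marks over the same genome:

1. **SE calling** (mark-agnostic). Peaks within a stitching distance
   *d* = 12.5 kb are merged; each stitched region is scored by its summed
   reads-over-input signal; the SE/TE cutoff is the point on the ascending
   rank–signal curve where a line of slope (max − min)/N — slope 1 after
   scaling both axes to [0, 1] — leaves the fewest points strictly below it.
2. **Preference groups.** Every region in the union of both marks' peaks is
   scored by log₂((ρ_A + 1)/(ρ_B + 1)), where ρ is per-kb signal density,
   and binned into six groups: groups 1–2 (log₂FC < −1) are mark-B-preferred,
   groups 5–6 (log₂FC > 1) mark-A-preferred. Regions are promoters when
   their anchor lies within 1 kb of a TSS, else enhancers.
3. **Colocalization.** Quadrant (strong/weak × strong/weak) 2×2 tables of
   paired signals with sample odds ratio and a two-sided Fisher exact test;
   per-group coverage fractions by a binding factor's peaks; treatment
   response of a peak set (lost / decreased / increased / unchanged).
4. **Gene association.** Nearest-TSS assignment, and basal-plus-extension
   regulatory domains (5 kb upstream / 1 kb downstream, extended up to 1 Mb,
   truncated at neighbouring basal domains).
5. **Expression integration.** CPM scaling, a simplified Welch-on-log-CPM
   differential-expression table with Benjamini–Hochberg FDR (external DE
   tables can be substituted), DE classification at FDR 0.05 and
   |log₂FC| > 0.5, Spearman signal–expression correlation, and Welch's
   t-test comparing per-gene expression fold changes between preference
   groups.
6. **Synthetic data.** A generator that plants all of the above structure —
   SE clusters, preference groups, factor co-binding with a chosen odds
   ratio, treatment effects concentrated on the most preferred group — and
   emits both the standard-format input files and a ground-truth record, so
   every stage has parameter-recovery tests.

Inputs are plain text formats: ENCODE narrowPeak, BED3/6, bedGraph, TSV
(TSS tables and count matrices). Coordinates are 0-based half-open
throughout.

## Worked example

Generate a synthetic dataset (500 typical peaks, 5 planted SE clusters at
50× signal, 300 genes, two replicates per condition) and run the full
pipeline:

```sh
acetrank simulate --seed 1 --out data/
acetrank se-call --peaks data/mark_a_peaks.narrowPeak \
                 --signal data/mark_a_control.bedGraph --out se/mark_a
```

which prints

```
{"n_regions": 505, "n_superenhancers": 6, "cutoff_signal": 606.19, "cutoff_index": 499}
```

— the 540 peaks stitch into 505 regions, and 6 exceed the geometric cutoff:
the 5 planted clusters (ranks 1–5, recovered with Jaccard 1.0 against the
planted spans) plus one high-signal singleton. The full pipeline
(`acetrank run --config run.yaml`, or `acetrank.pipeline.run_pipeline`)
additionally reports, for the same seed:

```
preference groups: {1: 31, 2: 76, 3: 161, 4: 158, 5: 85, 6: 29}
group 6 vs group 1 expression shift: t = -4.45, p = 8.9e-05
```

i.e. 94% of regions land in their planted preference group despite the
0.25-SD log₂FC jitter, and genes whose promoters are most mark-A-preferred
(group 6, planted mean treatment log₂FC −1) are significantly more
downregulated than group-1 genes — the negative Welch t says the first
group named is the more repressed one. `acetrank report out/report.json`
pretty-prints these numbers from any run.

## Layout

- `src/acetrank/io_formats.py` — formats, coordinate conventions, `SignalTrack`
- `src/acetrank/signal_quant.py` — region densities, RPM scaling, profile matrices
- `src/acetrank/se_caller.py` — stitching, geometric cutoff, SE calling
- `src/acetrank/preference.py` — six-group classification, set algebra
- `src/acetrank/colocalization.py` — quadrant odds ratios, coverage, peak response
- `src/acetrank/gene_assoc.py` — nearest-TSS and basal-plus-extension association
- `src/acetrank/expression_stats.py` — CPM, DE stand-in, BH, Welch, Spearman
- `src/acetrank/synthetic_data.py` — generator and truth-recovery reports
- `src/acetrank/pipeline.py`, `cli.py` — config-driven driver and `acetrank` CLI

See `docs/methods.md` for the model, parameter and design details.
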