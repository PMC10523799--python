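# Methods

## Coordinate and signal conventions

All regions are 0-based half-open (BED convention); TSS positions live on
the same axis and 1-based sources must be converted at parse time.
Chromosome names match by exact string equality — no "chr" aliasing — so
mismatched inputs fail loudly rather than silently dropping regions.

Coverage is modelled as a piecewise-constant track (`SignalTrack`), the
natural reading of a bedGraph. The per-region quantities are

- raw signal: Σ over base pairs of the track value,
- density: raw / region length in kb,
- corrected density: max(0, sample density − input density).

Input correction is subtraction with a floor at zero, matching the
reads-over-input ranking semantics of the reference SE-calling procedure;
ratio-based correction is deliberately not offered, because the ranking
statistic downstream assumes non-negative signals on a linear scale. When
library sizes are known, both sample and input tracks should be RPM-scaled
(`rpm_scale`) before subtraction so that libraries of different depth are
comparable. Replicated peak sets are reduced with `reproducible_peaks`:
peaks overlapping across the two replicates are kept with averaged signal.

bedGraph is the reference signal path so the whole pipeline runs on plain
text; a bigWig-backed track can be substituted by any object implementing
the same `integral`/`cumulative_at` interface.

## Super-enhancer calling

Peaks whose gap (next start − previous end) is at most the stitch distance
(default 12,500 bp) are merged transitively into candidate enhancers.
Optionally, peaks fully contained in TSS ± 2,500 bp can be removed before
stitching (off by default). Stitched regions are scored with the
input-corrected summed signal over the stitched span (densities are
reported alongside).

The SE/TE boundary is geometric. Sort the N signals ascending into v₁…v_N
(negatives floored to 0) and set s = (max − min)/N, the slope that equals 1
after scaling both axes to the unit square. For every candidate index x,
count the points strictly below the line of slope s through (x, v_x); the
cutoff index minimises that count and the cutoff signal is v at that index.
Regions strictly above the cutoff signal are SEs. Details that matter:

- Ties at the argmin resolve to the smallest index. Smaller index means a
  lower cutoff and therefore the larger SE set; the choice is deterministic
  and documented rather than dependent on optimizer internals.
- If all signals are equal the cutoff is that value and no region is an SE.
- The rule is invariant to multiplying all signals by c > 0 (both v and s
  scale by c), so SE labels do not depend on the signal units.
- `cutoff_index` is reported 1-based (the rank in the ascending order).
- Fewer than two stitched regions is an error: a cutoff needs a curve.

The caller is mark-agnostic: SEs ranked by a co-activator's binding signal
are the same operation on that factor's peaks and track.

## Preference groups

For a region carrying two marks with densities ρ_A and ρ_B,

log₂FC = log₂((ρ_A + 1)/(ρ_B + 1))

with pseudocount 1.0 on both sides (configurable) so zero-signal regions
stay finite. The six groups partition the line; boundary values follow the
printed interval wording of the grouping they implement:

| group | log₂FC          | reading            |
|-------|-----------------|--------------------|
| 1     | < −2            | most B-preferred   |
| 2     | −2 ≤ fc < −1    |                    |
| 3     | −1 ≤ fc < 0     |                    |
| 4     | 0 ≤ fc ≤ 1      | (0 and 1 included) |
| 5     | 1 < fc ≤ 2      |                    |
| 6     | > 2             | most A-preferred   |

"A-preferred" = groups 5–6, "B-preferred" = groups 1–2. The grid is not
symmetric at 0/1 (group 4 owns both endpoints), so swapping the marks maps
groups 1↔6 and 2↔5 exactly but can shift assignments at the inner
boundaries; the classifier and its tests treat only the outer mirror as an
invariant. The region universe for classification is the merged union of
both marks' peaks, each quantified from both tracks; the density-over-region
convention is recorded in the output.

Positional classification: a region is a promoter when its anchor (summit
if present, else midpoint) lies within 1,000 bp of the nearest TSS,
boundary inclusive. Set comparisons count a region as shared when the
shared span with the other set's union is at least 1 bp (configurable), the
intersect-default criterion; multi-set comparisons report element-wise
membership signatures so per-set totals always equal set sizes.

## Colocalization statistics

Quadrant analysis dichotomises two paired signals at per-signal thresholds
(default: the median of each signal, always recorded in the output, since a
published quadrant plot rarely prints its dotted lines). The association
statistic is the sample odds ratio n₁₁n₂₂/(n₁₂n₂₁), reported as +∞ when a
denominator cell is zero (a Haldane +0.5 correction is available by flag
but off by default so the printed statistic keeps its usual convention).
The two-sided Fisher exact p-value sums, at fixed margins, the
hypergeometric probabilities of all tables no more probable than the
observed one (with the customary 1 + 10⁻⁷ relative guard against
floating-point ties). The enumeration is computed in-package from
log-gamma terms; the test suite verifies it exhaustively against an
independent hypergeometric enumeration for every table with all margins
≤ 30 and against reference statistical software on random tables.

Per-group factor coverage is the fraction of group members overlapping any
factor peak by ≥ 1 bp (empty groups report NaN). Treatment response of a
peak set classifies each control peak as lost (no overlapping treated
peak), else decreased/increased/unchanged by the log₂ ratio of treated to
control region density with pseudocount 1 at a ±0.5 threshold.

## Gene association

Nearest-TSS assignment breaks distance ties by lexicographically smaller
gene id (deterministic); signed distances are positive downstream of the
TSS in the gene's orientation. Basal-plus-extension domains give each gene
a strand-aware basal region (5 kb upstream, 1 kb downstream) extended up to
1 Mb per side but stopped at the adjacent genes' basal boundaries (by TSS
order per chromosome) and chromosome bounds. Basal domains may overlap;
extension never shrinks below the basal region. The curated per-gene
exceptions maintained by the web-based implementation of this rule are not
reproducible from published tables and are not implemented. A region
associates with every gene whose extended domain it overlaps by ≥ 1 bp —
association is deliberately one-to-many.

## Expression statistics

Counts are scaled to counts-per-million per sample. The built-in DE test
is a deliberately simple stand-in for a negative-binomial count model:
Welch's t on log₂(CPM + 0.5) across replicates, BH-adjusted, classified at
FDR < 0.05 and |log₂FC| > 0.5. With 2–3 replicates this test is strongly
conservative — at negative-binomial dispersion 0.1 the per-replicate
log₂-CPM standard deviation is ≈ 0.46, so a 2-fold change yields t ≈ 2.7 at
df ≈ 4 and essentially no BH-significant calls; even an oracle z-test with
known variance would recall well under half of such genes at FDR 0.05.
The stand-in is therefore honest about *classification* (thresholding,
grouping, shift tests) while deferring *power* to dedicated count-model
tools: the pipeline accepts a precomputed external DE table
(gene, log2fc, p, fdr) wherever the internal one is used. Effect estimates
(log₂FC) from the stand-in are accurate and unbiased, which is what the
downstream group-shift analysis consumes.

Group expression shift: genes associated with regions of two preference
groups (each gene once per group) are compared on their per-gene log₂ FCs
with Welch's t (Welch–Satterthwaite df, two-sided p); negative t means the
first group is the more downregulated. When replicate-level fold changes
are supplied, `mean_replicate_fc` averages them per gene first. Spearman
correlations use average ranks for ties; constant vectors return NaN with
a warning rather than raising.

## Synthetic data generator

The generator emulates a two-mark, treated-vs-control acetylation study:

- **Geometry.** Peak units (isolated typical peaks and SE clusters) are
  placed sequentially per chromosome with random gaps of 25–60 kb — always
  above the stitch distance, so each unit is its own stitched region and
  region-level truth stays analytic. Cluster units hold 8 peaks inside an
  8 kb span (below the stitch distance, so a cluster stitches whole).
  Tracks are rectangular pulses of height density/1000 over each peak and
  zero elsewhere; background noise is deliberately absent so that every
  region signal equals its planted value exactly.
- **Preference.** Each peak draws a group from the configured proportions
  by deterministic largest-remainder allocation (exact group sizes) and a
  target log₂FC = group centre (−2.5 … +2.5) + N(0, jitter) with jitter
  sd 0.25 by default. The two mark densities split a base log-normal
  density geometrically, (ρ + 1) · 2^(±t/2) − 1, so the pseudocounted
  log-ratio equals the target exactly; at jitter 0 classification recovery
  is exact by construction, and recovery degrades monotonically with
  jitter.
- **SEs.** Cluster peaks carry 50× the typical base density, mirroring the
  order-of-magnitude signal concentration that defines SEs.
- **Factor.** A co-binding factor binds each peak with a group-graded
  probability rising from 0.13 (group 1) to 0.26 (group 6) — the twofold
  coverage asymmetry the preference analysis is designed to detect — and
  is depleted by treatment with probability 0.95 per bound peak.
- **Expression.** A subset of typical peaks carry a TSS within ±300 bp of
  their summit; the gene's log₂ mean count is a baseline (2⁸ counts) plus
  0.2 × the standardized promoter signal (giving a signal–expression
  Spearman around 0.5, the moderate genome-wide coupling typical of such
  designs), and treatment shifts it by a per-group effect — default
  (0, 0, 0, −0.2, −0.5, −1), i.e. downregulation concentrated on the most
  A-preferred group — plus N(0, 0.3) per-gene heterogeneity. Counts are
  negative binomial with variance μ + 0.1 μ², two replicates per condition.
- **Determinism.** All randomness flows from one integer seed; coordinates
  are integers and serialized signals are rounded to 6 decimals, so outputs
  are byte-identical across runs and platforms.
- **Quadrant recovery.** `simulate_quadrant` plants an exact odds ratio by
  solving the 2×2 cell probabilities from the margins and the OR, drawing
  multinomial counts, and emitting weak values on [0, 1) and strong values
  on [2, 3) with thresholds at 1.5 — the dichotomy recovers the planted
  table exactly, isolating estimator behaviour from threshold placement.

What the generator does **not** emulate: read-level sampling noise,
fragment-size and GC effects, background coverage between peaks, overlapping
or nested peaks across marks (both marks share one region universe),
copy-number variation, and promoter/enhancer interactions beyond the single
planted promoter peak per gene. Passing recovery tests therefore
demonstrate the correctness of the algorithms under clean planted structure,
not robustness to every artefact of real ChIP-seq data.

## Pipeline and problem sizes

The driver runs load → SE calling per mark → SE set comparison →
preference classification (with gene attachment: nearest gene for
promoters, domain association for enhancers) → colocalization → gene
association → expression, writing each stage's table plus a JSON report
with parameters and input checksums; any failure aborts with the stage
name and leaves a FAILED marker. Reports round floats to 6 decimals and
sort keys, so identical inputs give byte-identical outputs.

Default simulation sizes (500 typical peaks, 5 clusters, 300 genes, two
15 Mb chromosomes) keep a full end-to-end run around two seconds while
leaving every per-group sample size large enough for the recovery checks;
the acceptance script measures coverage and depletion fractions on a
3,000-peak simulation for tighter binomial error, and odds-ratio recovery
on 20,000 planted pairs where the analytic standard error
√(Σ 1/n_ij) of the log odds ratio is ≈ 0.05.

## Known limitations

- The DE stand-in's power limitation above; inject external count-model
  results for real studies.
- The quadrant thresholds default to medians; a sparse signal (zero on most
  regions) makes the median 0 and the table degenerate — set explicit
  thresholds (`params.quadrant_thresholds`) in that situation.
- Basal-plus-extension truncation uses TSS-adjacent neighbours per
  chromosome, which can differ from implementations that truncate against
  all other genes' domains in rare interleaved-gene layouts.
- `reproducible_peaks` keeps replicate-1 intervals as the reference
  geometry; a symmetric merge is not offered.
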