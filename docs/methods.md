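# Methods

## The data model

A section is a gene-by-pixel matrix of UMI counts on a square grid with
10 µm pitch; pixel labels encode the grid coordinates. The label dialect is
`"<x>x<y>"` with 0-based non-negative integers, x = column, y = row,
origin top-left, y drawn downward in figures (section-image convention).
Real deposited matrices do not document their label encoding, so the
parser is isolated in one function and the dialect is a declared
convention, not a claim about any particular archive. All distances are
computed in pixel units — the depth statistic below is scale-free — and
the physical pitch is carried only for axis annotation.

## Preprocessing

QC keeps exactly the pixels whose total count meets a threshold
(default 100; the appropriate value depends on capture efficiency and is
logged with every run). Normalization is log library-size scaling,
`value = log(1 + count × s / total)` with `s = 10,000`: deterministic,
dependency-free, and sufficient for everything downstream, which is
rank-based or difference-of-means throughout. Zero counts map to exactly
zero; the per-pixel scale makes values invariant to library-size
rescaling.

## Module scoring

For a gene set, all genes in the matrix are ordered by mean normalized
expression (ties broken by symbol) and split into `n_bins = 24`
equal-frequency bins. Each module gene draws up to `n_ctrl = 100` control
genes uniformly without replacement from its own bin, excluding itself
(self-matching would bias small universes). The pixel's score is the
average over module genes of (gene value − mean of its controls).

Averaging per-gene differences, rather than pooling every control into one
multiset, is deliberate: the equal-frequency split leaves some bins one
gene larger than others, and the remainder falls systematically at one end
of the expression ordering, so a pooled-control mean underweights the
controls of module genes from the smaller (high-expression) bins. On data
with no module signal this produced a measurable positive bias in pooled
scores; the per-gene form is identical when bins are equal and unbiased
when they are not. Scores are exactly shift-invariant and reproducible for
a fixed seed; random gene sets on null data are centred at zero (property
test, 200 random sets).

## Annotation and marker detection

Cell typing scores every candidate type's marker panel as a module and
assigns each pixel the argmax, recording the top-minus-runner-up margin;
exact ties go to the lexicographically first type and are flagged. The
rule-based refinement relabels every pixel whose normalized value of a
diagnostic gene exceeds a threshold (the code-level counterpart of
reassigning *SYCP3*-expressing cells to the meiotic cluster). In the
bundled pipeline this rule is applied within the germ-labelled pixels
only — a single diagnostic gene cannot separate meiotic germ cells from
sampling background tissue-wide at realistic depths (one background UMI
already yields a large log-normalized value) — with a default threshold of
4.5, about three UMIs at 300 counts/pixel.

Marker detection runs per cluster, one-vs-rest. Genes are screened first:
in-cluster expression fraction ≥ 10 % (fraction of pixels with a nonzero
value) and log2 fold change ≥ 0.5, computed on expm1-backtransformed means
with a 1e-9 pseudocount — the threshold convention is standard, the exact
formula rarely stated, so it is documented here and isolated in code.
Screened genes get a two-sided Wilcoxon rank-sum test on normalized
values. BH correction treats the full gene universe as the family for each
cluster's comparison, with screened-out genes entering at p = 1. This
matches the convention of the standard marker-detection routines (which
correct over all genes in the object) and is what makes the realized
false-discovery rate controllable: correcting only within the screened set
conditions on having survived a fold-change screen that itself selects for
extremity, and label-permutation experiments showed that family yields a
~46 % false-discovery fraction among the (very few) genes it tests. With
the universe-wide family the permutation false-discovery fraction is ~0–2 %
at BH 0.05. Only positive markers are reported; `top_markers` returns the
k = 5 largest significant fold changes per cluster, ties by symbol.

## Boundary-referenced depth

`depth_i = dist_i / D`. `dist_i` is the minimum Euclidean distance from
pixel *i* to a reference set of boundary pixels; `D` is the section
diameter. Choices the formula leaves open:

- **Reference set.** A manually supplied list takes precedence (mirroring
  hand-labelled outermost pixels, and allowing a mesonephros-abutting edge
  to be excluded via a mask); otherwise the boundary is extracted
  automatically as the pixels with fewer than four 4-neighbors inside the
  tissue.
- **Diameter.** `D` is the maximum pairwise Euclidean distance among the
  section's pixels (the caliper reading of "diameter"), computed per
  section, with a manual override for a measured value. For sections
  above 2,000 pixels the maximum is taken over convex-hull vertices, with
  a brute-force fallback for degenerate (collinear) sets.
- **Metric.** Continuous Euclidean distance between pixel centers, not
  city-block.
- **One boundary.** A two-boundary (cortex/medulla) normalization would
  also be defensible; the implementation follows the printed single-
  reference formula.

Depth is translation-invariant, scale-invariant (dist and D scale
together), zero exactly on reference pixels, and bounded by 0.5 for convex
sections. Stage-wise testing compares consecutive stages with two-sided
rank-sum tests, BH-adjusts across the comparisons, annotates the standard
star tiers (\*< 0.05, \*\*< 0.01, \*\*\*< 0.001, \*\*\*\*< 1e-4, ns
otherwise on adjusted p) and reports whether stage means decrease strictly
along the stage order. Consecutive-stage comparisons are the default;
all-pairs would also be reasonable and can be assembled from `ranksum`
directly.

## Niche analysis

The vicinity of a target pixel is Chebyshev distance ∈ [1, r] on grid
coordinates, default r = 1 — the eight surrounding pixels, the minimal
reading of a grid vicinity that excludes the central point. Neighborhoods
are collected per section (a neighbor never crosses sections), pooled over
targets, deduplicated, and the targets appended to form the final
selection. Composition tallies the neighbor pixels only: a pixel that is
both a target and another target's neighbor counts once, as a target, and
stays out of the tally, because the question is which *somatic* cells
surround the germ cells — a flag-level design choice users can flip by
tallying `final_ids` instead. Proportions are counts over the group total
within (target subtype, stage); replicate sections of a stage pool
naturally through the selection list.

## The synthetic generator

The generator is the package's verification instrument: it emulates the
features of a stratified fetal-ovary section that the estimators consume,
with ground truth exact by construction.

- **Geometry.** An axis-aligned ellipse of grid pixels (default circular,
  150×150 grid ≈ 17,400 tissue pixels). Zone assignment reuses the
  *estimator's* boundary, diameter and depth code, so generator and
  estimator share one geometry definition. The default is circular
  because the depth statistic's ceiling is `b/(2a)` for an ellipse with
  semi-axes `a ≥ b` — only near-circular sections can host the deepest
  stage target (0.45) at all.
- **Zones.** Relative depth (depth / max depth) bands: outer cortex
  [0, 0.22) dominated by surface-epithelium cells, inner cortex
  [0.22, 0.50) dominated by second-wave pregranulosa, medulla [0.50, 1]
  with first-wave pregranulosa, interstitial and endothelial cells. A
  lateral strip (leftmost 10 % of the x-extent) is overridden to a
  mesenchymal-dominated "interface" zone, standing in for the one-sided
  gonad–mesonephros interface.
- **Germ placement.** Per stage, germ pixel counts (default 300, split
  across subtypes in a stage-appropriate way: mitotic-only at E24 through
  RA + meiotic at E50) and a target mean normalized depth (0.45, 0.35,
  0.25, 0.18, 0.10). Pixels are drawn with a Gaussian kernel around the
  target depth, then refined by deterministic greedy swaps until the
  realized mean is within ±0.01 of target (±0.02 guaranteed); infeasible
  requests fail loudly, naming the stage and attainable band. This makes
  migration-recovery truth exact rather than distributional.
- **Counts.** Negative binomial with mean
  `nb_mean × gene-baseline × folds` and dispersion θ
  (variance = µ + µ²/θ). Defaults: `nb_mean = 1.0` (≈ 300 UMIs per pixel,
  typical high-definition spatial depth), per-gene lognormal baselines
  (σ = 0.7) fixed by the blueprint seed so a gene keeps its baseline
  across stages, θ = 2 (strong overdispersion), marker fold 10 on each
  type's 8-gene panel, module folds 3 on zone-restricted BMP-like and
  RA-like gene sets, plus 150 background genes.
- **Truth.** Per-pixel zone/type/subtype/depth; per-subtype adjacency
  proportions computed by an independent brute-force offset scan (not the
  estimator's KDTree path); per-subtype realized depth means. Identical
  (blueprint, stage, seed) triples give byte-identical fixtures.

What the generator does **not** emulate: segmentation artifacts and
doublets, spatial autocorrelation of library size, bleed-over between
adjacent pixels, irregular (non-convex) section outlines, and real
marker-gene co-expression structure. Passing recovery tests therefore
demonstrates that the estimators are correct and calibrated under a
faithful stylized model — not that annotation accuracy or niche error on
real sections will match these numbers.

## Determinism and reporting

Every stochastic step takes an explicit seed; batch operations derive
per-item seeds from one stream. The pipeline (`run_all`) writes TSV/JSON
artifacts that are byte-identical across reruns with the same config and
seed — which is why the run manifest records config echo, seeds, input
hashes, output list and version, while stage timings go to the log rather
than the manifest. Figures are byproducts; nothing quantitative is
asserted on rendered images.

## Problem sizes

Defaults were chosen so a full verification pass (test suite plus the
acceptance script) completes in a few minutes on one CPU: 150×150 sections
for recovery experiments, 64×64 for unit-level generator checks, 2,000
replicates for rank-sum calibration, 20 label permutations for
false-discovery control, 200 random gene sets for module-score centring.

## Statistical kernels

`ranksum` uses the exact Mann–Whitney null for pooled n ≤ 20 without ties
and the tie-corrected normal approximation otherwise, continuity
correction off so perfectly exchangeable inputs give p = 1 exactly; exact
p-values are cross-checked against full enumeration in the tests, and the
null rejection rate at α = 0.05 is calibrated to [0.04, 0.06] over 2,000
replicates. `bh_adjust` is the standard step-up with running minimum,
order-preserving. Tests are two-sided by default; the zone-recovery checks
use the one-sided alternative because the direction is hypothesized.
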