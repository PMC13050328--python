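# spatgonad

Pixel-grid spatial transcriptomics analysis of stratified fetal gonads.

High-definition spatial RNA-seq captures a tissue section as a grid of
10 µm barcoded pixels, each with a UMI count vector — near single-cell
resolution with exact spatial coordinates encoded in the pixel labels.
In the developing ovary this makes a classic question quantitative: *where*
are the fetal germ cells (FGCs) relative to the cortical surface, how does
that position shift as mitotic primordial germ cells specify into
retinoic-acid-responsive and then meiotic oogonia, and which somatic cells
(surface epithelium, two pregranulosa waves, interstitial, endothelial,
mesenchymal) form their immediate niche at each stage?

`spatgonad` implements that analysis pipeline as a tested Python library:

- **grid I/O** — decode gene-by-pixel count matrices whose pixel labels
  encode grid coordinates (`"<x>x<y>"` dialect), Matrix Market on disk;
- **preprocess** — pixel QC by total counts; log library-size
  normalization `log(1 + c·s/total)`;
- **module scoring** — per-pixel gene-set scores against expression-matched
  control genes drawn from equal-frequency expression bins;
- **annotation** — cell typing by argmax of marker-panel module scores,
  rule-based subtype reassignment (e.g. *SYCP3*⁺ → meiotic), and
  one-vs-rest Wilcoxon marker detection with the conventional screens
  (expression fraction ≥ 10 %, log2FC ≥ 0.5) and Benjamini–Hochberg
  correction;
- **spatial depth** — the boundary-referenced statistic
  `depth_i = dist_i / D`, where `dist_i` is the minimum Euclidean distance
  from pixel *i* to the labelled outer boundary and `D` the section
  diameter (max pairwise distance), plus stage-wise rank-sum testing of
  the depth decline;
- **niche analysis** — Chebyshev-radius grid neighborhoods around target
  pixels (center excluded, per-section, deduplicated) and cell-type
  composition of the surrounding pixels;
- **synthetic gonad** — a generator producing stratified sections with
  concentric zones, negative-binomial counts, spiked markers,
  zone-restricted pathway modules and germ cells placed to an exact
  per-stage mean-depth target, so every stage of the pipeline can be
  verified against known ground truth.

## Worked example

`examples/02_depth_migration.py` simulates one section per developmental
stage (E24–E50), estimates every pixel's normalized depth and tests the
stage-wise decline for germ pixels:

```
germ mean depth per stage (0 = at the surface, 0.5 = dead centre):
E24    0.440
E27    0.340
E30    0.246
E35    0.177
E50    0.098

strictly decreasing: True

consecutive-stage comparisons (rank-sum, BH-adjusted):
stage_a stage_b  mean_a  mean_b  adj_p stars
    E24     E27  0.4400  0.3404    0.0  ****
    E27     E30  0.3404  0.2464    0.0  ****
    E30     E35  0.2464  0.1772    0.0  ****
    E35     E50  0.1772  0.0980    0.0  ****
```

The recovered stage means sit on the blueprint's targets (0.45, 0.35,
0.25, 0.18, 0.10) to within the generator's ±0.02 guarantee, the decline
is strictly monotone, and every consecutive comparison is significant —
the cortical-migration signature, recovered from raw counts.

The other examples cover section simulation (`01`), annotation and marker
recovery (`03`, ~98 % agreement with truth at the default conditions),
pathway-module zone recovery (`04`) and niche composition (`05`).

A thin CLI wraps the same functions (`spatgonad simulate|qc|normalize|
score|annotate|markers|depth|niche|report|run-all`); `spatgonad run-all
--seed 0 --outdir run` executes the full synthetic study and writes
deterministic TSV/JSON artifacts plus a manifest.

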