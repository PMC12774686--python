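# Methods

## Data model

The pipeline starts from segmented cells, not images. Each cell carries
its centroid in μm (image convention: origin top-left, y downward,
1 px = 1 μm) and per-marker pixel fractions in [0, 1] — the share of the
cell's segmentation-mask pixels classified positive for the marker, so
0.5 means half the cell stains positive. Cells are grouped into ROIs
(imaged rectangles), each with an annotated basalis tissue area in mm²
that is the denominator of all densities; the area is an input field,
never re-derived. Segmentation masks are not consumed: cells are points,
and all distances are centroid-to-centroid. Tools that dilate masks to
define contact use boundary distances instead; keeping the radius
configurable (default 10 μm) is the compensating knob.

## Phenotyping

Marker positivity is `pixel_fraction >= threshold` with threshold 0.25
by default. The cut is applied per cell to already-binarized pixel
fractions; 0.25 tolerates partial-cell staining (a nucleus-adjacent
marker filling a quarter of the mask still calls positive) while stray
pixels do not. It is exposed in `MarkerPanel` and on every CLI.

Cells with no positive marker at all ("blank" cells) are excluded
before any statistic, and the excluded count is logged and recorded in
the run manifest so the step is auditable.

Lineage gating is a fixed Boolean hierarchy: HLA-G⁺ → trophoblast
(taking precedence over everything, since extravillous trophoblasts can
pick up ambient immune markers); otherwise CD45 is required for any
immune lineage; within immune cells the priority order
myeloid (CD68⁺ or CD14⁺) > T (CD3⁺) > NK (CD56⁺ and CD7⁺) >
granulocyte (CD15⁺) resolves conflicts; T cells split into CD4⁺, CD8a⁺
and double-negative (dnT). Unmatched cells are `unassigned` and drop
out of the phenotype universe.

The twelve decidual myeloid clusters are encoded as an explicit rule
table (required-positive / required-negative marker sets). Phrases of
the form "solely positive for X" become explicit negativity for the
sibling cluster's extra markers, which makes the rules mutually
exclusive exactly where the descriptions are. Matching is
most-specific-wins (largest constraint count), ties broken by table
order; myeloid cells matching no rule are `unclassified` rather than
forced into a cluster. A coarse CD163⁺HLA-DR⁺ myeloid gate (covering
dM1, dM2, dM4, dM5, dM10) is provided independently of the cluster
table because the six-marker immunofluorescence panel can only resolve
that phenotype. Gating is vectorised and row-order independent.

## Microenvironment statistic

For an ordered pair (A, B) within one ROI:

* **observed%** — share of A-cells with at least `min_neighbors`
  (default 1) B-cells within the radius, ×100. The neighbour relation
  is symmetric (unordered pairs at distance ≤ r, no self-pairs; KD-tree
  search, verified against the O(n²) distance matrix), but observed% is
  deliberately asymmetric because it conditions on A.
* **expected%** — B's frequency among all phenotype-assigned cells of
  the ROI, ×100. This is a frequency correction, not a spatial null: an
  abundant partner phenotype is expected in many microenvironments by
  chance.
* **corrected = observed% − expected%** — the quantity compared across
  samples and groups. Note corrected is *not* centred at zero under
  random labelling (observed depends on cell density, expected only on
  frequency), so calibration claims are made through the permutation z,
  never through corrected ≈ 0.
* **permutation z** — K (default 1000, minimum 100) shuffles of the
  complete label vector over the fixed positions, within each ROI
  independently, preserving the label multiset; observed% is recomputed
  each time and z = (obs − mean)/SD (SD with ddof = 1). |z| > 1.96
  flags non-random proximity. K = 1000 gives a z resolution of ~0.03.
  The shuffle RNG is seeded from the spec, so z-scores reproduce to all
  digits.

Degenerate cases propagate as flagged missing values, never zeros: no
source cells → observed undefined (NaN); permutation SD = 0 (e.g. a
single-phenotype ROI) → z undefined and not significant.

**Sample-level pooling.** The per-sample value pools a sample's ROIs by
source-cell count: pooled observed% = 100 · Σ hits / Σ n_A, pooled
expected% = assigned-cell-weighted mean. Cells, not ROIs, are the
units, matching the per-cell semantics of the percentages; a pooled
sample is numerically identical to concatenating its ROIs with
ROI-disjoint adjacency (tested). Each permutation replicate permutes
within ROIs and pools the same way. The expected% denominator is the
per-ROI assigned-cell universe by default; restricting the universe
(e.g. immune cells only) amounts to relabelling before the call.

**Row z-matrix.** For heatmap summaries the pair × sample matrix of
corrected values is row-standardised: (x − row mean)/row SD with
ddof = 1; zero-SD rows are returned as zeros and flagged. The matrix is
emitted both before and independent of permutation filtering, since
either convention may be wanted downstream.

## Inference

Group sizes of 4–11 make asymptotic Mann-Whitney p-values unreliable,
so the null distribution of U is computed exactly: counts of all
C(n1+n2, n1) assignments per U value via the Gaussian-binomial
recurrence with exact integer arithmetic (a dynamic program, not
literal enumeration; literal enumeration is the test oracle). U counts
pairs with x < y plus half-ties, so U = 0 means group 1 fully dominant.
The two-sided p is the doubled smaller tail, clamped at 1 — the
convention of standard exact-test software; the alternative (summing
opposite-tail probabilities ≤ the observed one) differs in edge cases
and is intentionally not used. Ties or n1+n2 > 20 fall back to a seeded
permutation test (10⁵ resamples default) with an explicit method flag;
corrected-enrichment percentages are continuous, so real comparisons
are effectively tie-free.

Cliff's delta is (#{x>y} − #{x<y})/(n1·n2), oriented group1 − group2
with the first-listed group first. `cliffs_delta_from_U` converts a
published U to |δ| = |1 − 2U/(n1·n2)| and signs it by an explicit
dominant-group argument, because published U values often follow the
smaller-of-the-two convention that discards the sign.

Fisher's exact test (standard two-sided rule) and Spearman correlation
delegate to scipy behind this module's surface; the hypergeometric
enumeration oracle in the tests keeps the delegation honest. Bonferroni
multiplies by the family size m (which may exceed the number of
supplied p-values) and clamps at 1; the default family in the pipeline
is all group comparisons of one metric.

`mwu_power_sim` estimates the power of the exact two-sided MWU at a
target Cliff's δ under a normal location-shift parent calibrated so
P(X>Y) = (1+δ)/2 (shift μ = √2·Φ⁻¹((1+δ)/2)). It is a probe with
explicit knobs (parent model, α, group sizes), not a reproduction of
any particular published power figure, whose computation details are
typically unstated.

## Synthetic cohorts

The generator emulates exactly the structure the statistics consume:

* Cell count ~ Poisson(density × basalis area), positions uniform on
  the ROI rectangle (CSR is the positional null; Ripley-K at 10 μm is
  checked against a Monte-Carlo CSR envelope in the tests). Default
  density 1000 cells/mm² with a frequency vector making myeloid cells
  65% of immune cells and ≈520 myeloid cells/mm² — the composition
  regime of term decidua.
* Phenotypes i.i.d. from the frequency vector: trophoblast 20%, and an
  immune compartment of three myeloid clusters (dM1 16%, dM5 20%,
  dM9 16%), CD4 T 9.6%, CD8 T 6.4%, NK 8%, granulocyte 4%.
* Attraction by relocation (parent–child construction): per rule
  (A, B, π, r_a), each B-cell is moved with probability π to a uniform
  point in the r_a-disk around a uniformly chosen A-anchor, clipped to
  the ROI edge (no torus — real tissue has edges). This is simple,
  seedable, and produces precisely the proximity signal the corrected
  enrichment measures, monotonically in π. It does not model
  interaction potentials, repulsion, or higher-order structure.
* Marker fractions ~ Beta(8, 4) for profile-positive markers
  (mode 0.7, P(< 0.25) ≈ 0.001) and Beta(2, 28) for negative
  (mode ≈ 0.04, P(≥ 0.25) ≈ 0.0025). With ~13 decisive negative
  markers on the strictest gate the per-cell misgating probability
  stays ≈3%, so default gating recovers ≥95% of generating labels
  (measured ≈98%).
* Determinism: every ROI draws from an RNG seeded by (master seed,
  sample index, ROI index); equal seeds give byte-identical CSVs, and
  distinct samples never share a stream.

The built-in 4-vs-4 scenario (two 1.4 mm square ROIs per sample,
≈2000 cells each; π = 0.6 at r_a = 8 μm for CD4 T → dM1/dM5 in one
group, π = 0 in the other) produces corrected enrichments of ≈ +7 vs
≈ −7 percentage points — complete separation (U = 0, δ = 1,
p = 0.029) in virtually every seed.

What the generator does *not* emulate: segmentation errors, marker
spillover, pixel-level noise, spatially varying density (glands,
vessels), within-sample ROI heterogeneity, or correlated marker
expression beyond the Boolean profiles. Passing tests therefore
demonstrate correctness of the statistical machinery under the model's
own assumptions, not robustness to the artefacts of real imaging data.

## Numerical and design conventions

* Positivity and neighbourhood inclusion are both `≥`/`≤` at the
  boundary (a cell exactly at threshold is positive; cells exactly
  10 μm apart are neighbours).
* Permutation calibration is assessed where the permutation null is
  approximately normal (mean neighbour-hit count ≳ 30). In sparse
  regimes (mean hits ≲ 5) the discrete, skewed null makes |z| > 1.96
  conservative — a property of z-thresholding, inherent to the method.
* Exact-p path requires integer U (tie-free); non-integer U raises
  rather than silently rounding.
* All pipeline outputs are CSV/JSON; the run manifest stores the config
  hash, seed, version and gating audit counts. Stage seeds derive from
  the master seed via named seed sequences, so partial re-runs
  reproduce.

## Problem sizes used in the checks

The end-to-end checks run the 4-vs-4 scenario over 20 master seeds
(~2000 cells/ROI, 16 ROIs per run), the permutation calibration over
500 ROIs of ≈600 cells at K = 1000, and the attraction-recovery sweep
over π ∈ {0, 0.2, …, 1} with 20 replicates of a single 1 mm² ROI —
sizes chosen to match the cohort scale the package targets while
keeping the full suite runnable on a laptop in well under an hour.

## Known limitations

* Centroid distances understate contact between large, irregular cells;
  radius tuning only partially compensates.
* The expected% correction is a frequency null, not a spatial null;
  density gradients within an ROI can move corrected values without any
  pairwise interaction. The permutation z is the guard against reading
  such shifts as interactions.
* The myeloid cluster table is a faithful Boolean transcription of
  textual cluster descriptions; real marker distributions are
  continuous, and cells near thresholds will fall through to
  `unclassified` rather than being assigned by similarity.
* Exact MWU requires tie-free data; heavily discretised metrics will
  silently route to the permutation fallback (flagged in `method`).
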