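# Methods

## The annotation model

marrowmap treats annotation as supervised mapping onto a frozen reference,
in the style of reference-mapping tools for single-cell data. The atlas
stores everything needed to reproduce its embedding: the HVG list, per-gene
scaling parameters (mean, sd of the log-normalized values), an orthonormal
PC basis obtained by SVD of the scaled reference matrix, per-cell PC scores
and a 2D layout. A query sample is scaled with the *stored* parameters and
multiplied through the stored basis; nothing is refit per query. This makes
annotation deterministic, O(n_cells) fast, and exactly self-consistent:
projecting the reference's own cells reproduces its PC scores to machine
precision, and k = 1 label transfer returns the stored labels identically.

Assumptions this rests on:

- query and reference share gene nomenclature and a broadly similar
  capture technology (HVGs missing from the query are zero-filled; more
  than 50% missing aborts, since absent features cannot be imputed);
- the reference covers the cell states present in the query. There is no
  open-set rejection: a genuinely novel cell type will be assigned to its
  nearest reference compartment with low confidence, not flagged.

kNN vote with k = 15 balances noise suppression against boundary blur at
reference sizes of a few thousand cells; confidence is the raw vote
fraction, so `confidence * k` is always an integer in [1, k]. Ties break to
the label of the nearest tied neighbor, which keeps transfer deterministic
and permutation-equivariant. Distances are unweighted Euclidean in the full
PC space; eigenvalue weighting was left out to keep the contract simple.

## Taxonomy

The default taxonomy has 14 marrow compartments, with an 8-type "major"
subset used for cropped myeloid maps. Lineage assignment drives the
myeloid/lymphoid (M/L) ratio: committed granulo-monocytic output (GMP,
pro-neutrophil, neutrophil, monocyte, cDC) over lymphocytes (T, NK, B,
plasma). HSPC, MEP, Eryp, erythrocytes and pDC are lineage "other" so the
ratio contrasts committed myelopoiesis against the lymphoid compartment;
pDC in particular is excluded from the numerator because pDC expansions
(seen in inflammatory comorbidity) would otherwise masquerade as myeloid
output. All of this lives in an editable taxonomy file, not in code.

Risk stratification is a single threshold: a sample is called high-risk
when its mature-myeloid fraction (pro-neutrophils + neutrophils +
monocytes) is strictly below 0.10. The threshold is a tunable clinical
dial (`--risk-threshold`), echoed into every output for provenance.

## Reference construction

HVGs are selected by mean-binned normalized dispersion (the classic
Seurat-v1 recipe): per-gene dispersion var/mean of the log-normalized
values, z-scored within 20 quantile bins of mean expression, top n taken
with ties broken by symbol. Constant genes are dropped with a warning.
Scaled values are clipped at ±10 standard deviations so rare transcripts
cannot dominate a component. The PC basis comes from full SVD with a
deterministic sign convention (the largest-magnitude loading of each
component is positive), which makes atlas builds bit-reproducible.

Two layouts are supported. `pc12` (the first two PC scores) is exactly
reproducible and adequate for references with a handful of well-separated
types. The packaged demo atlas instead uses the seeded UMAP embedding of
the PC scores: with 14 balanced compartments, two principal components
cannot give every type its own territory on the map, and the density
analytics — which integrate sample mass over a cell type's territory —
need that separation. UMAP runs with a fixed `random_state`, so demo-atlas
builds are deterministic for a given seed and environment.

Atlases serialize to a plain-text directory (JSON + TSV at full float
precision), and the round trip is bit-exact.

## Density maps

Each annotated sample becomes a product-Gaussian KDE evaluated on a
grid_size² grid spanning the atlas layout bounding box padded 5% per side.
The grid comes from the atlas, never the sample, so all maps on one atlas
share a canvas and subtract node-by-node. Per-axis bandwidth follows
Scott's rule for two dimensions, h = n^(−1/6)·sd, with a fallback to 5% of
the axis range (with a warning) when an axis has zero variance. Node masses
are renormalized to sum to exactly 1; a difference map therefore sums to ~0
and its integral over a label set's territory (grid nodes whose nearest
reference cell carries one of those labels) measures compositional
displacement between samples. Rendering to PNG is a thin optional layer;
the numeric grid is the product.

## Statistics

Two-group comparisons use the two-sided Wilcoxon rank-sum (Mann–Whitney)
test — exact null distribution when the combined n ≤ 20, normal
approximation with continuity correction above — or Welch's t-test, chosen
explicitly by flag; normality is not auto-detected. Significance stars
follow the strict convention `**** < 1e-4 ≤ *** < 1e-3 ≤ ** < 0.01 ≤ * <
0.05 ≤ n.s.`. No multiple-testing correction is applied by default, since
comparison tables report raw per-metric stars; with cohorts of a few
samples per group the exact test's granularity (smallest two-sided p at
3 vs 3 is 0.1) matters more than correction. Mutation burden is normalized
per cell — mutations divided by cells in the sample — and nothing more;
variant calling itself is out of scope.

## Signature scores

Module scores are signature mean minus bin-matched control mean. Genes are
cut into 24 near-equal quantile bins of average expression (ties broken by
symbol; remainders land in the lowest bins); for each signature gene 100
control genes are drawn from its bin, excluding signature genes, without
replacement when the bin allows it. Defaults (24 bins, 100 controls)
follow the widely used Seurat configuration; both are flags.

One design choice deserves a note: `module_score` accepts a precomputed
gene→bin assignment. When bins are recomputed from a perturbed matrix, a
shift applied to signature genes moves them across expression bins and
changes the control pools, so scores are only approximately shift-
equivariant. Pinning the bin structure (computed on a baseline matrix)
makes the algebra exact — adding δ to every signature gene adds exactly δ
to every score, and scaling the matrix by λ scales scores by λ — which is
what the invariant tests verify. The default, matching common practice,
still derives bins from the matrix at hand. The four shipped example
signatures are random draws from the synthetic gene panel, named
`synthetic_*`; real analyses should supply curated sets via GMT.

## The synthetic generator

The generator emulates marrow *composition phenotypes*, not marrow
transcriptomes. Each of the 14 types owns 20 dedicated marker genes
(disjoint across types) boosted by e² ≈ 7.4-fold over a flat baseline of
0.1 expected counts/gene on a 1,500-gene panel; per-cell library factors
are lognormal (meanlog 0, sdlog 0.35, a typical droplet depth spread);
counts are Poisson, with an optional gamma-Poisson (negative binomial)
dispersion dial. Labels are categorical draws from a preset composition.
Everything is seeded and bit-reproducible, and every moment used in tests
has a closed form.

Preset compositions encode the ordinal facts of the disease groups —
high-risk MDS: mature-myeloid share 0.07 with elevated HSPC; low-risk MDS:
mature share 0.31 with elevated HSPC; healthy: mature share 0.40; AML-like:
HSPC+GMP 0.70 — chosen once as plausible marrow numbers. They are editorial
values, not measurements.

What the generator does *not* model: gene–gene correlation within a type,
continuous differentiation trajectories, doublets, ambient RNA, batch
effects, or mitochondrial content (no `MT-` genes exist on the panel, so
the mito QC rule is exercised only by dedicated fixtures). Passing the
recovery tests therefore shows the pipeline's machinery is correct under
its own assumptions — separable types, honest labels — not that real
marrow annotation reaches the same accuracy.

Because the panel has 1,500 genes at base rate 0.1, a cell detects ~150
genes in expectation; synthetic runs therefore use `min_genes_per_cell=50`,
while the real-data default stays at 200 (with `max_mito_fraction=0.15`
and `min_cells_per_gene=3`), thresholds chosen as common practice and
always recorded in the QC report.

## Numerical choices and degenerate inputs

- QC is two-stage by definition (cells first, then genes). It is a fixed
  point in practice, but not formally idempotent: removing rare genes can
  push a borderline cell below the detected-gene threshold on a second
  pass. Knife-edge inputs are the user's to avoid; the report records both
  stages.
- `normalize_log1p` errors on zero-count cells rather than silently
  emitting zeros; zero entries stay exactly 0.
- The M/L ratio returns flagged +inf (warning: "undefined-denominator")
  when a sample has no lymphoid cells, and errors only when both sums are
  zero, so tables always render.
- Layout imputation uses weights 1/(d + 1e-9); a query identical to a
  reference cell recovers that cell's coordinates to ~1e-6.
- Gene-symbol collisions are resolved by numeric suffixing (`ACTB.1`),
  preserving feature count.

## Problem sizes

The demo atlas is 300 cells/type × 14 types = 4,200 cells with 1,000 HVGs
and 30 PCs; recovery experiments annotate 5,000-cell query samples;
statistical calibration uses 2,000 null replicates at 10 vs 10; density
grids default to 200×200. These sizes give stable statistics (multinomial
noise on a 5,000-cell fraction is ~0.4 percentage points) while keeping a
full rebuild-and-verify cycle under a minute on a laptop core.

## Known limitations

- No batch/chemistry correction: systematic query-vs-reference shifts move
  cells in PC space and bias votes.
- No open-set detection (leukemic blasts map to their nearest healthy
  compartment).
- Density comparisons are descriptive; no differential-abundance test is
  attached to the grids.
- Leave-one-out label recovery on the demo atlas is ~92%; confusions are
  concentrated among transcriptionally adjacent progenitor compartments,
  which is the expected failure mode of unweighted kNN at cluster borders.
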