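# marrowmap

Reference-based annotation and composition profiling of bone-marrow
scRNA-seq samples.

Unsorted bone-marrow aspirates profiled by single-cell RNA-seq contain the
whole hematopoietic hierarchy — stem and progenitor cells (HSPC), committed
progenitors (GMP, MEP, Eryp), mature myeloid output (pro-neutrophils,
neutrophils, monocytes), dendritic cells, erythroid cells and lymphocytes.
In myelodysplastic syndrome (MDS) and related disorders the *shape* of that
composition is diagnostic: high-risk marrow is depleted of mature myeloid
cells and enriched for HSPCs. marrowmap is for hematology groups who want
to annotate new marrow samples against a fixed reference atlas in seconds
and read disease state off the resulting composition — without re-running a
full unsupervised clustering per sample.

## What it computes

Given a labeled **reference atlas** — highly variable genes (HVGs) with
per-gene scaling parameters (μ_g, σ_g), an orthonormal PC basis **W**
(n_hvg × n_pcs) and a 2D layout — a query sample is processed as:

1. **QC + normalization**: cells with few detected genes or high
   mitochondrial fraction are removed, then rarely detected genes;
   counts are LogNormalized, `x_gj = ln(1 + c_gj / Σ_g c_gj · 10⁴)`.
2. **Projection**: query HVG expression is scaled with the *stored*
   reference parameters, `z = clip((x − μ)/σ, ±10)`, and projected,
   `pc = z·W`. Reference parameters are never refit on the query.
3. **Label transfer**: each cell takes the majority label of its k = 15
   Euclidean nearest reference neighbors in PC space; confidence is the
   winning vote fraction; ties break to the nearest tied neighbor.
4. **Layout imputation**: query cells are placed on the reference map at
   the inverse-distance-weighted mean of their neighbors' coordinates.
5. **Density maps**: each sample becomes a unit-mass product-Gaussian KDE
   on a grid fixed by the atlas bounds, so maps subtract node-by-node.
6. **Composition analytics**: per-type fractions, the mature-myeloid
   fraction (Pro_Neutrophil + Neutrophil + Monocyte), the myeloid/lymphoid
   ratio, a threshold risk call (high-risk iff mature-myeloid fraction
   < 0.10), per-cell mutation burden (mutations / cells), and two-group
   tests (exact Wilcoxon rank-sum or Welch t) with the star convention
   `* p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001`.
7. **Signature scores**: per-cell module scores — mean expression of a
   gene set minus the mean of expression-bin-matched control genes.

A synthetic-data module generates labeled marrow samples with known
composition (presets: `healthy`, `MDS_high`, `MDS_low`, `AML_like`) and
marker structure, and builds the packaged 4,200-cell demo atlas, so the
whole pipeline is testable end to end with closed-form ground truth.

## Worked example

```bash
python examples/annotate_sample.py
```

annotates a 3,000-cell synthetic high-risk MDS sample on the demo atlas
and prints (abridged):

```
cell type        recovered   truth
HSPC                 0.147   0.150
Pro_Neutrophil       0.024   0.020
Neutrophil           0.035   0.030
Monocyte             0.023   0.020
T                    0.247   0.270
...
mature myeloid fraction: 0.081  -> risk call: MDS_high
myeloid/lymphoid ratio:  0.459
mean label confidence:   0.779
```

Recovered fractions track the generating composition within ~2 percentage
points; the mature-myeloid share below 0.10 triggers the high-risk call.
`examples/density_contrast.py` shows the same depletion spatially — the
healthy-minus-MDS density difference carries `+0.211` mass over the
mature-myeloid territory of the map — and `examples/composition_cohort.py`
runs a 9-sample cohort through the full pipeline (4 healthy / 3 high-risk /
2 low-risk, all risk calls correct; at 4-vs-3 samples the smallest exact
rank-sum p is 0.057, hence `n.s.`). `examples/signature_scoring.py` scores
the generator's T-cell markers: +1.91 in T cells vs −0.40 elsewhere.

There is also a CLI for shell use:

```bash
marrowmap demo-ref --out atlas/
marrowmap simulate --preset MDS_high --cells 5000 --seed 7 --out query/
marrowmap annotate --query query/ --atlas atlas/ --out ann.tsv \
    --min-genes-per-cell 50 --min-cells-per-gene 1
marrowmap run --demo --out run_out/   # full demo cohort
```

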