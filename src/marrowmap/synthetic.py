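"""Synthetic bone-marrow samples with known composition and marker structure.

The generator emulates the compositional phenotypes of marrow disease
groups — not real marrow transcriptomes. Each cell type owns a disjoint
set of marker genes boosted by a common log fold change over a flat
baseline; counts are Poisson (optionally negative binomial) around
library-size-scaled rates, so every expectation used in tests has a closed
form. Presets encode the ordinal facts of the disease groups: both MDS
presets have elevated HSPC shares; the high-risk preset has a mature-
myeloid share below the 0.10 risk threshold; the AML-like preset is
dominated by blast-like HSPC/GMP.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .io import CountMatrix, normalize_log1p
from .reference import ReferenceAtlas, Taxonomy, build_reference, default_taxonomy

#: Editorial preset compositions satisfying the groups' ordinal phenotypes.
PRESET_COMPOSITIONS: dict[str, dict[str, float]] = {
    "healthy": {
        "HSPC": 0.04, "GMP": 0.05, "MEP": 0.03, "Eryp": 0.05,
        "Pro_Neutrophil": 0.08, "Neutrophil": 0.20, "Monocyte": 0.12,
        "pDC": 0.01, "cDC": 0.02, "Erythrocyte": 0.05,
        "T": 0.20, "NK": 0.05, "B": 0.08, "Plasma": 0.02,
    },
    # mature myeloid (Pro_Neutrophil+Neutrophil+Monocyte) = 0.07 < 0.10
    "MDS_high": {
        "HSPC": 0.15, "GMP": 0.08, "MEP": 0.05, "Eryp": 0.10,
        "Pro_Neutrophil": 0.02, "Neutrophil": 0.03, "Monocyte": 0.02,
        "pDC": 0.03, "cDC": 0.01, "Erythrocyte": 0.08,
        "T": 0.27, "NK": 0.07, "B": 0.07, "Plasma": 0.02,
    },
    # elevated HSPC but near-healthy mature-myeloid output (0.31)
    "MDS_low": {
        "HSPC": 0.12, "GMP": 0.06, "MEP": 0.04, "Eryp": 0.07,
        "Pro_Neutrophil": 0.06, "Neutrophil": 0.15, "Monocyte": 0.10,
        "pDC": 0.01, "cDC": 0.02, "Erythrocyte": 0.06,
        "T": 0.20, "NK": 0.05, "B": 0.05, "Plasma": 0.01,
    },
    # dominant blast-like compartment: HSPC+GMP = 0.70
    "AML_like": {
        "HSPC": 0.45, "GMP": 0.25, "MEP": 0.03, "Eryp": 0.04,
        "Pro_Neutrophil": 0.02, "Neutrophil": 0.03, "Monocyte": 0.04,
        "pDC": 0.01, "cDC": 0.01, "Erythrocyte": 0.03,
        "T": 0.04, "NK": 0.02, "B": 0.02, "Plasma": 0.01,
    },
}

PRESET_GROUP = {"healthy": "healthy", "MDS_high": "MDS_high",
                "MDS_low": "MDS_low", "AML_like": "AML"}


@dataclass
class GeneratorSpec:
    """Parameters of one synthetic marrow sample.

    marker_log_fc is in natural-log units: markers of a cell's own type are
    boosted by exp(marker_log_fc). base_mean is the expected count per
    non-marker gene at library factor 1. Library factors are lognormal.
    dispersion=None draws Poisson counts; a positive value phi switches to
    negative binomial via gamma-Poisson mixing (var = mu + phi*mu^2).
    """

    composition: dict[str, float]
    taxonomy: Taxonomy = field(default_factory=default_taxonomy)
    n_cells: int = 5000
    n_genes: int = 1500
    markers_per_type: int = 20
    marker_log_fc: float = 2.0
    base_mean: float = 0.1
    lib_meanlog: float = 0.0
    lib_sdlog: float = 0.35
    dispersion: float | None = None
    seed: int = 0
    sample_id: str = "synthetic"

    def __post_init__(self) -> None:
        comp = np.array([self.composition.get(l, 0.0) for l in self.taxonomy.labels])
        if np.any(comp < 0) or not np.isclose(comp.sum(), 1.0):
            raise ValueError("composition must be non-negative and sum to 1")
        if self.n_genes < len(self.taxonomy.labels) * self.markers_per_type:
            raise ValueError("n_genes too small to hold disjoint marker sets")
        if self.base_mean <= 0 or self.marker_log_fc < 0:
            raise ValueError("rates must be positive")


def gene_names(n_genes: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n_genes)]


def marker_table(spec: GeneratorSpec) -> dict[str, list[str]]:
    """Disjoint marker genes per label: the first m*n_labels genes, in
    taxonomy order."""
    names = gene_names(spec.n_genes)
    m = spec.markers_per_type
    return {
        label: names[i * m:(i + 1) * m]
        for i, label in enumerate(spec.taxonomy.labels)
    }


def simulate_sample(spec: GeneratorSpec) -> tuple[CountMatrix, np.ndarray]:
    """Draw one labeled sample: labels ~ categorical(composition), counts ~
    Poisson(base_mean * library_factor * marker_boost). Fully seeded."""
    rng = np.random.default_rng(spec.seed)
    labels_order = list(spec.taxonomy.labels)
    comp = np.array([spec.composition.get(l, 0.0) for l in labels_order])
    label_idx = rng.choice(len(labels_order), size=spec.n_cells, p=comp)
    lib = rng.lognormal(spec.lib_meanlog, spec.lib_sdlog, size=spec.n_cells)

    m = spec.markers_per_type
    boost = np.exp(spec.marker_log_fc)
    rates = np.full((spec.n_genes, spec.n_cells), spec.base_mean)
    for t in range(len(labels_order)):
        cols = label_idx == t
        rates[t * m:(t + 1) * m, cols] *= boost
    rates *= lib[None, :]

    if spec.dispersion:
        shape = 1.0 / spec.dispersion
        rates = rng.gamma(shape, rates / shape)
    counts = rng.poisson(rates)

    cm = CountMatrix(
        genes=gene_names(spec.n_genes),
        cells=[f"{spec.sample_id}-C{i:05d}" for i in range(spec.n_cells)],
        counts=sp.csr_matrix(counts),
        sample_id=spec.sample_id,
    )
    return cm, np.array([labels_order[t] for t in label_idx])


def preset_spec(name: str, n_cells: int = 5000, seed: int = 0,
                sample_id: str | None = None, **overrides) -> GeneratorSpec:
    if name not in PRESET_COMPOSITIONS:
        raise ValueError(f"unknown preset {name!r}; choose from "
                         f"{sorted(PRESET_COMPOSITIONS)}")
    return GeneratorSpec(
        composition=dict(PRESET_COMPOSITIONS[name]),
        n_cells=n_cells, seed=seed,
        sample_id=sample_id or f"{name}-s{seed}",
        **overrides,
    )


def simulate_preset(name: str, n_cells: int = 5000, seed: int = 0,
                    sample_id: str | None = None) -> tuple[CountMatrix, np.ndarray]:
    return simulate_sample(preset_spec(name, n_cells=n_cells, seed=seed,
                                       sample_id=sample_id))


@dataclass
class ReferenceFixture:
    """A demo atlas plus the inputs it was built from."""

    atlas: ReferenceAtlas
    counts: CountMatrix
    norm: sp.csr_matrix
    labels: np.ndarray


def make_reference_fixture(
    seed: int = 0,
    cells_per_type: int = 300,
    n_genes: int = 1500,
    n_hvg: int = 1000,
    n_pcs: int = 30,
    layout: str = "umap",
) -> ReferenceFixture:
    """Balanced 14-type reference (default 4,200 cells) built end to end:
    simulate -> normalize -> build_reference. The packaged demo atlas.

    The layout defaults to the seeded UMAP embedding: with 14 compartments,
    the first two PCs alone do not give each type its own territory on the
    map, which the density analytics rely on. Pass layout="pc12" for a
    layout that is exactly the first two PC scores.
    """
    taxonomy = default_taxonomy()
    n_types = len(taxonomy.labels)
    n_cells = cells_per_type * n_types
    spec = GeneratorSpec(
        composition={l: 1.0 / n_types for l in taxonomy.labels},
        taxonomy=taxonomy,
        n_cells=n_cells,
        n_genes=n_genes,
        seed=seed,
        sample_id="reference",
    )
    # exactly balanced labels (round-robin) rather than a categorical draw,
    # so every type contributes cells_per_type cells to the atlas
    labels = np.array([taxonomy.labels[i % n_types] for i in range(n_cells)])
    rng = np.random.default_rng(seed)
    lib = rng.lognormal(spec.lib_meanlog, spec.lib_sdlog, size=n_cells)
    m = spec.markers_per_type
    boost = np.exp(spec.marker_log_fc)
    rates = np.full((n_genes, n_cells), spec.base_mean)
    for t, label in enumerate(taxonomy.labels):
        rates[t * m:(t + 1) * m, labels == label] *= boost
    rates *= lib[None, :]
    counts = rng.poisson(rates)
    cm = CountMatrix(
        genes=gene_names(n_genes),
        cells=[f"ref-C{i:05d}" for i in range(n_cells)],
        counts=sp.csr_matrix(counts),
        sample_id="reference",
    )
    norm = normalize_log1p(cm)
    atlas = build_reference(
        norm, cm.genes, labels, taxonomy,
        n_hvg=n_hvg, n_pcs=n_pcs, layout=layout, seed=seed,
    )
    return ReferenceFixture(atlas=atlas, counts=cm, norm=norm, labels=labels)
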