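"""The labeled bone-marrow reference atlas and its hematopoietic taxonomy.

The atlas is a frozen embedding of labeled marrow cells: a highly-variable
gene (HVG) list with per-gene scaling parameters, an orthonormal PC basis
fit on the scaled reference expression, per-cell PC scores, and a 2D layout
used as the common canvas for density maps. Query samples are projected
with the *stored* scaling parameters and basis, never refit.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp

SCHEMA_VERSION = 1

MYELOID = "myeloid"
LYMPHOID = "lymphoid"
OTHER = "other"

#: The 14 marrow compartments of the default taxonomy. Eleven are named in
#: the source atlas description (HSPC, GMP, MEP, Eryp, pro-neutrophil,
#: neutrophil, monocyte, pDC, T, NK, B); cDC, Erythrocyte and Plasma
#: complete the set as standard marrow compartments and are editable via
#: the taxonomy file rather than hard-coded truth.
DEFAULT_LABELS = (
    "HSPC", "GMP", "MEP", "Eryp",
    "Pro_Neutrophil", "Neutrophil", "Monocyte",
    "pDC", "cDC", "Erythrocyte",
    "T", "NK", "B", "Plasma",
)

_DEFAULT_LINEAGE = {
    "HSPC": OTHER, "GMP": MYELOID, "MEP": OTHER, "Eryp": OTHER,
    "Pro_Neutrophil": MYELOID, "Neutrophil": MYELOID, "Monocyte": MYELOID,
    "pDC": OTHER, "cDC": MYELOID, "Erythrocyte": OTHER,
    "T": LYMPHOID, "NK": LYMPHOID, "B": LYMPHOID, "Plasma": LYMPHOID,
}

_DEFAULT_MATURE_MYELOID = ("Pro_Neutrophil", "Neutrophil", "Monocyte")

#: Labels shown on the cropped myeloid reference map (8 major types).
_DEFAULT_MAP_MAJOR = (
    "HSPC", "GMP", "MEP", "Eryp", "Pro_Neutrophil", "Neutrophil",
    "Monocyte", "pDC",
)


@dataclass(frozen=True)
class Taxonomy:
    """Cell-type labels plus the lineage map used by composition metrics."""

    labels: tuple[str, ...]
    lineage: dict[str, str]
    mature_myeloid: frozenset[str]
    map_major: frozenset[str]

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate taxonomy labels")
        for lab in self.labels:
            if self.lineage.get(lab) not in (MYELOID, LYMPHOID, OTHER):
                raise ValueError(f"label {lab!r} lacks a valid lineage")
        myeloid = {l for l in self.labels if self.lineage[l] == MYELOID}
        if not self.mature_myeloid <= myeloid:
            raise ValueError("mature_myeloid must be a subset of myeloid labels")
        if not self.map_major <= set(self.labels):
            raise ValueError("map_major must be a subset of labels")

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "lineage": dict(self.lineage),
            "mature_myeloid": sorted(self.mature_myeloid),
            "map_major": sorted(self.map_major),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Taxonomy":
        return cls(
            labels=tuple(d["labels"]),
            lineage=dict(d["lineage"]),
            mature_myeloid=frozenset(d["mature_myeloid"]),
            map_major=frozenset(d["map_major"]),
        )


def default_taxonomy() -> Taxonomy:
    """The packaged 14-type marrow taxonomy with its 8-type major myeloid map.

    Mature myeloid = {pro-neutrophil, neutrophil, monocyte}: the compartments
    depleted in high-risk MDS. HSPC, MEP, Eryp, Erythrocyte and pDC carry
    lineage "other" so the myeloid/lymphoid ratio compares committed
    granulo-monocytic output against lymphocytes.
    """
    return Taxonomy(
        labels=DEFAULT_LABELS,
        lineage=dict(_DEFAULT_LINEAGE),
        mature_myeloid=frozenset(_DEFAULT_MATURE_MYELOID),
        map_major=frozenset(_DEFAULT_MAP_MAJOR),
    )


def lineage_fraction_sets(taxonomy: Taxonomy) -> tuple[set[str], set[str]]:
    """(myeloid labels, lymphoid labels) used by the M/L ratio."""
    myeloid = {l for l in taxonomy.labels if taxonomy.lineage[l] == MYELOID}
    lymphoid = {l for l in taxonomy.labels if taxonomy.lineage[l] == LYMPHOID}
    return myeloid, lymphoid


@dataclass
class ReferenceAtlas:
    taxonomy: Taxonomy
    cell_labels: np.ndarray          # (n_ref,) str
    hvg: list[str]                   # ordered HVG symbols
    gene_means: np.ndarray           # (n_hvg,)
    gene_sds: np.ndarray             # (n_hvg,)
    pc_loadings: np.ndarray          # (n_hvg, n_pcs), orthonormal columns
    pc_coords: np.ndarray            # (n_ref, n_pcs)
    layout2d: np.ndarray             # (n_ref, 2)
    target_sum: float = 1e4
    layout_method: str = "pc12"
    clip_value: float = 10.0

    def __post_init__(self) -> None:
        gram = self.pc_loadings.T @ self.pc_loadings
        if not np.allclose(gram, np.eye(gram.shape[0]), atol=1e-6):
            raise ValueError("pc_loadings columns are not orthonormal")
        known = set(self.taxonomy.labels)
        bad = set(map(str, self.cell_labels)) - known
        if bad:
            raise ValueError(f"cell labels not in taxonomy: {sorted(bad)}")

    @property
    def n_pcs(self) -> int:
        return self.pc_loadings.shape[1]

    @property
    def n_cells(self) -> int:
        return self.pc_coords.shape[0]

    # -- serialization: plain-text directory, bit-exact round trip ---------

    def save(self, dir_path: str | Path) -> None:
        d = Path(dir_path)
        d.mkdir(parents=True, exist_ok=True)
        (d / "taxonomy.json").write_text(json.dumps(self.taxonomy.to_dict(), indent=1))
        (d / "meta.json").write_text(json.dumps({
            "schema_version": SCHEMA_VERSION,
            "n_hvg": len(self.hvg),
            "n_pcs": self.n_pcs,
            "target_sum": self.target_sum,
            "layout_method": self.layout_method,
            "clip_value": self.clip_value,
        }, indent=1))
        (d / "hvg.tsv").write_text("\n".join(self.hvg) + "\n")
        np.savetxt(d / "scaling.tsv",
                   np.column_stack([self.gene_means, self.gene_sds]),
                   fmt="%.17g", delimiter="\t", header="mean\tsd")
        np.savetxt(d / "loadings.tsv", self.pc_loadings, fmt="%.17g", delimiter="\t")
        np.savetxt(d / "pc_coords.tsv", self.pc_coords, fmt="%.17g", delimiter="\t")
        np.savetxt(d / "layout2d.tsv", self.layout2d, fmt="%.17g", delimiter="\t")
        (d / "labels.tsv").write_text("\n".join(map(str, self.cell_labels)) + "\n")

    @classmethod
    def load(cls, dir_path: str | Path) -> "ReferenceAtlas":
        d = Path(dir_path)
        meta = json.loads((d / "meta.json").read_text())
        if meta["schema_version"] != SCHEMA_VERSION:
            raise ValueError(f"unsupported atlas schema {meta['schema_version']}")
        taxonomy = Taxonomy.from_dict(json.loads((d / "taxonomy.json").read_text()))
        scaling = np.loadtxt(d / "scaling.tsv", delimiter="\t", ndmin=2)
        return cls(
            taxonomy=taxonomy,
            cell_labels=np.array((d / "labels.tsv").read_text().split("\n")[:-1]),
            hvg=(d / "hvg.tsv").read_text().split("\n")[:-1],
            gene_means=scaling[:, 0],
            gene_sds=scaling[:, 1],
            pc_loadings=np.loadtxt(d / "loadings.tsv", delimiter="\t", ndmin=2),
            pc_coords=np.loadtxt(d / "pc_coords.tsv", delimiter="\t", ndmin=2),
            layout2d=np.loadtxt(d / "layout2d.tsv", delimiter="\t", ndmin=2),
            target_sum=meta["target_sum"],
            layout_method=meta["layout_method"],
            clip_value=meta["clip_value"],
        )


def select_hvgs(norm_matrix: sp.spmatrix, genes: list[str], n_hvg: int,
                n_mean_bins: int = 20) -> list[str]:
    """Top-``n_hvg`` genes by mean-binned normalized dispersion.

    Dispersion = var/mean of the normalized values; genes are cut into
    ``n_mean_bins`` quantile bins of mean expression and dispersions are
    z-scored within each bin, so variability is judged against genes of
    similar abundance. Constant genes (sd = 0) are dropped with a warning.
    Ties break by gene symbol for determinism.
    """
    X = sp.csr_matrix(norm_matrix)
    n_cells = X.shape[1]
    means = np.asarray(X.mean(axis=1)).ravel()
    sq = np.asarray(X.multiply(X).mean(axis=1)).ravel()
    variances = np.maximum(sq - means**2, 0.0) * n_cells / max(n_cells - 1, 1)

    ok = variances > 0
    if (~ok).any():
        warnings.warn(f"dropping {(~ok).sum()} constant genes from HVG selection")
    idx = np.flatnonzero(ok)
    if len(idx) < n_hvg:
        raise ValueError(f"only {len(idx)} non-constant genes for n_hvg={n_hvg}")

    disp = variances[idx] / np.maximum(means[idx], 1e-12)
    order = np.argsort(means[idx], kind="stable")
    bins = np.array_split(order, min(n_mean_bins, len(order)))
    norm_disp = np.empty_like(disp)
    for b in bins:
        mu, sd = disp[b].mean(), disp[b].std()
        norm_disp[b] = (disp[b] - mu) / sd if sd > 0 else 0.0

    names = np.array(genes, dtype=object)[idx]
    ranked = sorted(zip(-norm_disp, names), key=lambda t: (t[0], t[1]))
    return [str(name) for _, name in ranked[:n_hvg]]


def _scale_clip(dense_cells_by_genes: np.ndarray, means: np.ndarray,
                sds: np.ndarray, clip: float) -> np.ndarray:
    return np.clip((dense_cells_by_genes - means) / sds, -clip, clip)


def build_reference(
    norm_matrix: sp.spmatrix,
    genes: list[str],
    cell_labels,
    taxonomy: Taxonomy,
    n_hvg: int = 2000,
    n_pcs: int = 30,
    layout: str = "pc12",
    seed: int = 0,
    target_sum: float = 1e4,
    clip_value: float = 10.0,
) -> ReferenceAtlas:
    """Fit the reference embedding on a log-normalized gene x cell matrix.

    HVGs are chosen by binned dispersion, z-scored with clipping at
    ±``clip_value``, and decomposed by SVD; deterministic sign convention
    (largest-magnitude loading positive per component). ``layout='pc12'``
    uses the first two PCs (fully deterministic); ``layout='umap'`` runs a
    seeded neighbor-graph embedding of the PC scores.
    """
    labels = np.asarray(cell_labels, dtype=object).astype(str)
    unknown = set(labels) - set(taxonomy.labels)
    if unknown:
        raise ValueError(f"labels not in taxonomy: {sorted(unknown)}")
    if len(set(labels)) < 2:
        raise ValueError("reference must cover at least 2 taxonomy labels")
    n_genes, n_cells = norm_matrix.shape
    if n_hvg > n_genes:
        raise ValueError(f"n_hvg={n_hvg} exceeds {n_genes} genes")
    if n_pcs >= min(n_hvg, n_cells):
        raise ValueError("n_pcs must be < min(n_hvg, n_cells)")
    if layout not in ("pc12", "umap"):
        raise ValueError(f"unknown layout {layout!r}")

    hvg = select_hvgs(norm_matrix, genes, n_hvg)
    gene_index = {g: i for i, g in enumerate(genes)}
    rows = [gene_index[g] for g in hvg]
    H = np.asarray(sp.csr_matrix(norm_matrix)[rows].todense()).T  # cells x hvg

    gene_means = H.mean(axis=0)
    gene_sds = H.std(axis=0, ddof=1)
    X = _scale_clip(H, gene_means, gene_sds, clip_value)

    _, _, vt = np.linalg.svd(X, full_matrices=False)
    loadings = vt[:n_pcs].T
    # sign convention: the largest-|loading| entry of each PC is positive
    flip = loadings[np.abs(loadings).argmax(axis=0), np.arange(n_pcs)] < 0
    loadings[:, flip] *= -1
    pc_coords = X @ loadings

    if layout == "pc12":
        layout2d = pc_coords[:, :2].copy()
    else:
        import umap  # deferred: slow import, only needed for this layout

        layout2d = umap.UMAP(random_state=seed, n_components=2).fit_transform(
            pc_coords
        ).astype(np.float64)

    return ReferenceAtlas(
        taxonomy=taxonomy,
        cell_labels=labels,
        hvg=hvg,
        gene_means=gene_means,
        gene_sds=gene_sds,
        pc_loadings=loadings,
        pc_coords=pc_coords,
        layout2d=layout2d,
        target_sum=target_sum,
        layout_method=layout,
        clip_value=clip_value,
    )
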