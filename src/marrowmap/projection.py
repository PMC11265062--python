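"""Project query cells onto the reference atlas and transfer labels.

The annotation core: query cells are scaled with the atlas's stored
per-gene parameters, projected through its PC basis, labeled by k-nearest-
neighbor majority vote in PC space, and placed on the reference 2D layout
by inverse-distance-weighted neighbor averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .io import CountMatrix, QCReport, normalize_log1p, qc_filter
from .reference import ReferenceAtlas, _scale_clip

GROUPS = ("healthy", "MDS_high", "MDS_low", "AML", "other")


class FeatureMismatchError(ValueError):
    """Raised when too few atlas HVGs are present in the query."""


@dataclass
class AnnotatedSample:
    """Per-cell annotation of one query sample on a reference atlas."""

    sample_id: str
    group: str
    cell_ids: list[str]
    pc_coords: np.ndarray   # (n, n_pcs)
    layout2d: np.ndarray    # (n, 2)
    label: np.ndarray       # (n,) str
    confidence: np.ndarray  # (n,) in (0, 1]
    qc_report: QCReport | None = None
    missing_hvg_fraction: float = 0.0

    def __post_init__(self) -> None:
        n = len(self.cell_ids)
        for name in ("pc_coords", "layout2d", "label", "confidence"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"{name} row count != {n} cells")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}")
        if len(self.confidence) and (
            self.confidence.min() <= 0 or self.confidence.max() > 1
        ):
            raise ValueError("confidence must lie in (0, 1]")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cell_id": self.cell_ids,
            "label": self.label,
            "confidence": self.confidence,
            "x": self.layout2d[:, 0],
            "y": self.layout2d[:, 1],
            "sample_id": self.sample_id,
            "group": self.group,
        })


def align_features(
    query_norm: sp.spmatrix, query_genes: list[str], atlas: ReferenceAtlas,
    max_missing: float = 0.5,
) -> tuple[np.ndarray, float]:
    """Reorder a normalized query matrix to the atlas HVG list.

    Returns a dense cells x n_hvg array plus the fraction of atlas HVGs
    absent from the query. Missing genes are zero-filled (absence cannot
    fabricate signal); more than ``max_missing`` missing aborts.
    """
    gene_index = {g: i for i, g in enumerate(query_genes)}
    n_hvg = len(atlas.hvg)
    present = [(j, gene_index[g]) for j, g in enumerate(atlas.hvg) if g in gene_index]
    missing_fraction = 1.0 - len(present) / n_hvg
    if missing_fraction > max_missing:
        raise FeatureMismatchError(
            f"query/reference feature mismatch: {missing_fraction:.0%} of "
            f"{n_hvg} atlas HVGs missing from query"
        )
    X = sp.csr_matrix(query_norm)
    aligned = np.zeros((X.shape[1], n_hvg))
    cols, rows = zip(*present)
    aligned[:, list(cols)] = np.asarray(X[list(rows)].todense()).T
    return aligned, missing_fraction


def project_cells(aligned_query: np.ndarray, atlas: ReferenceAtlas) -> np.ndarray:
    """Scale with the atlas's stored gene means/sds (clipped) and project.

    The reference scaling parameters are always used — never recomputed
    from the query — so the query lands in the same PC space as the atlas.
    """
    X = _scale_clip(aligned_query, atlas.gene_means, atlas.gene_sds,
                    atlas.clip_value)
    return X @ atlas.pc_loadings


def _knn(query_pc: np.ndarray, atlas: ReferenceAtlas, k: int):
    if k <= 0:
        raise ValueError("k must be a positive integer")
    if k > atlas.n_cells:
        raise ValueError(f"k={k} exceeds {atlas.n_cells} reference cells")
    nn = NearestNeighbors(n_neighbors=k, metric="euclidean")
    nn.fit(atlas.pc_coords)
    return nn.kneighbors(query_pc)  # distances, indices (sorted by distance)


def transfer_labels(
    query_pc: np.ndarray, atlas: ReferenceAtlas, k: int = 15,
) -> tuple[np.ndarray, np.ndarray]:
    """Majority-vote kNN label transfer in PC space.

    Confidence is the winning vote fraction (in [1/k, 1]). A tied vote is
    broken by the label of the nearest neighbor among the tied labels.
    """
    dist, idx = _knn(query_pc, atlas, k)
    neigh_labels = atlas.cell_labels[idx]  # (n, k), nearest first
    labels = np.empty(len(query_pc), dtype=object)
    confidence = np.empty(len(query_pc))
    for i in range(len(query_pc)):
        uniq, counts = np.unique(neigh_labels[i], return_counts=True)
        top = counts.max()
        tied = set(uniq[counts == top])
        if len(tied) == 1:
            labels[i] = next(iter(tied))
        else:
            labels[i] = next(l for l in neigh_labels[i] if l in tied)
        confidence[i] = top / k
    return labels.astype(str), confidence


def impute_layout(
    query_pc: np.ndarray, atlas: ReferenceAtlas, k: int = 15, eps: float = 1e-9,
) -> np.ndarray:
    """Inverse-distance-weighted average of the k nearest reference cells'
    layout coordinates; the result lies in their convex hull."""
    dist, idx = _knn(query_pc, atlas, k)
    w = 1.0 / (dist + eps)
    w /= w.sum(axis=1, keepdims=True)
    return np.einsum("nk,nkd->nd", w, atlas.layout2d[idx])


def annotate_sample(
    cm: CountMatrix,
    atlas: ReferenceAtlas,
    group: str = "other",
    k: int = 15,
    qc_params: dict | None = None,
    eps: float = 1e-9,
) -> AnnotatedSample:
    """Full annotation: QC -> normalize -> align -> project -> label -> layout.

    Deterministic end to end; QC thresholds default to the package QC
    defaults and are recorded in the returned sample's QCReport.
    """
    filtered, report = qc_filter(cm, **(qc_params or {}))
    norm = normalize_log1p(filtered, target_sum=atlas.target_sum)
    aligned, missing = align_features(norm, filtered.genes, atlas)
    pc = project_cells(aligned, atlas)
    labels, confidence = transfer_labels(pc, atlas, k=k)
    layout = impute_layout(pc, atlas, k=k, eps=eps)
    return AnnotatedSample(
        sample_id=cm.sample_id,
        group=group,
        cell_ids=filtered.cells,
        pc_coords=pc,
        layout2d=layout,
        label=labels,
        confidence=confidence,
        qc_report=report,
        missing_hvg_fraction=missing,
    )
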