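"""Bin-matched control scoring of gene signatures (module scores).

A cell's score for a signature is its mean normalized expression over the
signature genes minus the mean over a pool of control genes drawn from the
same average-expression bins, so abundance alone cannot inflate a score.
This is the standard Seurat-style module score; the binning and tie rules
here are fully deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp


@dataclass(frozen=True)
class GeneSignature:
    name: str
    genes: tuple[str, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("signature must contain at least one gene")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature gene symbols must be unique")


@dataclass
class SignatureScores:
    signature: str
    cells: list[str]
    scores: np.ndarray
    n_bins: int
    n_ctrl: int
    seed: int
    n_genes_used: int

    def to_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.cells, name=self.signature)


def bin_genes(gene_means: pd.Series, n_bins: int = 24) -> pd.Series:
    """Assign every gene to one of ``n_bins`` average-expression bins.

    Genes are ranked by (mean, symbol) — the symbol breaks ties — and cut
    into near-equal quantile bins; when n_genes % n_bins != 0 the remainder
    is spread over the lowest bins. Fewer genes than bins reduces n_bins
    with a warning.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    n = len(gene_means)
    if n == 0:
        raise ValueError("no genes to bin")
    if n < n_bins:
        warnings.warn(f"only {n} genes; reducing n_bins from {n_bins} to {n}")
        n_bins = n
    order = sorted(gene_means.index, key=lambda g: (gene_means[g], g))
    base, rem = divmod(n, n_bins)
    sizes = [base + 1] * rem + [base] * (n_bins - rem)
    bins = np.empty(n, dtype=int)
    start = 0
    for b, size in enumerate(sizes):
        bins[start:start + size] = b
        start += size
    return pd.Series(bins, index=order).reindex(gene_means.index)


def module_score(
    norm_matrix: sp.spmatrix,
    genes: list[str],
    cells: list[str],
    signature: GeneSignature,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    bins: pd.Series | None = None,
) -> SignatureScores:
    """Signature mean minus bin-matched control-pool mean, per cell.

    For each signature gene present in the matrix, ``n_ctrl`` control genes
    are drawn from its expression bin (uniformly without replacement, or
    with replacement when the bin holds fewer than ``n_ctrl`` candidates),
    excluding all signature genes. The control draws are pooled and the
    score is mean(signature expr) - mean(pooled control expr).

    ``bins`` overrides the expression binning (a gene -> bin Series from
    :func:`bin_genes`). Passing bins computed on a baseline matrix pins the
    control structure, which makes scores exactly equivariant under shifts
    of the signature genes; by default bins are recomputed from the matrix
    at hand.
    """
    X = sp.csr_matrix(norm_matrix)
    gene_index = {g: i for i, g in enumerate(genes)}
    sig_present = [g for g in signature.genes if g in gene_index]
    dropped = len(signature.genes) - len(sig_present)
    if not sig_present:
        raise ValueError(f"no gene of signature {signature.name!r} in matrix")
    if dropped:
        warnings.warn(f"{dropped} signature gene(s) absent from matrix, dropped")

    if bins is None:
        means = pd.Series(np.asarray(X.mean(axis=1)).ravel(), index=genes)
        bins = bin_genes(means, n_bins=n_bins)
    sig_set = set(sig_present)
    rng = np.random.default_rng(seed)

    ctrl_rows: list[int] = []
    for g in sig_present:
        pool = [c for c in bins.index[bins == bins[g]] if c not in sig_set]
        if not pool:
            warnings.warn(f"bin of {g} holds no non-signature genes; skipped")
            continue
        replace = len(pool) < n_ctrl
        picked = rng.choice(len(pool), size=n_ctrl, replace=replace)
        ctrl_rows.extend(gene_index[pool[i]] for i in picked)
    if not ctrl_rows:
        raise ValueError("no control genes available for any signature gene")

    sig_rows = [gene_index[g] for g in sig_present]
    sig_mean = np.asarray(X[sig_rows].mean(axis=0)).ravel()
    ctrl_mean = np.asarray(X[ctrl_rows].mean(axis=0)).ravel()
    return SignatureScores(
        signature=signature.name,
        cells=list(cells),
        scores=sig_mean - ctrl_mean,
        n_bins=n_bins,
        n_ctrl=n_ctrl,
        seed=seed,
        n_genes_used=len(sig_present),
    )


def read_gmt(path: str | Path) -> list[GeneSignature]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sigs = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"GMT line needs name, description, >=1 gene: {line!r}")
        # keep order, drop duplicates
        genes = tuple(dict.fromkeys(p for p in parts[2:] if p))
        sigs.append(GeneSignature(name=parts[0], genes=genes, provenance=parts[1]))
    return sigs


def example_signatures(genes: list[str], rng_seed: int = 0,
                       size: int = 15) -> list[GeneSignature]:
    """Synthetic placeholder signatures drawn from the supplied gene panel.

    Stand-ins for T-cell activity sets (inflammation, exhaustion,
    cytotoxicity, surveillance) whose published memberships are not shipped
    here; clearly non-canonical, for demos and tests only.
    """
    rng = np.random.default_rng(rng_seed)
    names = ["synthetic_inflammation", "synthetic_exhaustion",
             "synthetic_cytotoxicity", "synthetic_surveillance"]
    out = []
    for name in names:
        picked = rng.choice(len(genes), size=min(size, len(genes)), replace=False)
        out.append(GeneSignature(
            name=name,
            genes=tuple(genes[i] for i in sorted(picked)),
            provenance="synthetic placeholder (random draw from panel)",
        ))
    return out
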