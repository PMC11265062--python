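"""Per-sample density maps over the reference 2D layout.

Each annotated sample is rendered as a normalized Gaussian kernel density
on a grid derived from the *atlas* layout bounds (padded 5%), so maps from
different samples share an identical canvas and can be subtracted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .reference import ReferenceAtlas


@dataclass
class DensityMap:
    grid_x: np.ndarray      # (G,) node coordinates
    grid_y: np.ndarray      # (G,)
    mass: np.ndarray        # (G, G), mass[i, j] at (grid_x[i], grid_y[j]); sums to 1
    bandwidth: tuple[float, float]
    sample_id: str = ""

    def same_grid(self, other: "DensityMap") -> bool:
        return (
            self.grid_x.shape == other.grid_x.shape
            and np.array_equal(self.grid_x, other.grid_x)
            and np.array_equal(self.grid_y, other.grid_y)
        )


def atlas_grid(atlas: ReferenceAtlas, grid_size: int = 200,
               pad: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Grid nodes spanning the atlas layout bounding box, padded 5% per side."""
    lo = atlas.layout2d.min(axis=0)
    hi = atlas.layout2d.max(axis=0)
    span = hi - lo
    lo, hi = lo - pad * span, hi + pad * span
    return (np.linspace(lo[0], hi[0], grid_size),
            np.linspace(lo[1], hi[1], grid_size))


def _scott_bandwidth(values: np.ndarray, axis_range: float) -> float:
    h = len(values) ** (-1 / 6) * values.std()
    if h == 0:
        warnings.warn("zero-variance axis; falling back to 5% of axis range")
        h = 0.05 * axis_range
    return h


def density_map(
    points: np.ndarray,
    atlas: ReferenceAtlas,
    grid_size: int = 200,
    bandwidth: str | tuple[float, float] = "scott",
    sample_id: str = "",
) -> DensityMap:
    """Product-Gaussian KDE of layout points, renormalized over the grid.

    Scott's rule per axis: h = n^(-1/6) * sd. The kernel has no covariance
    term; node masses are divided by their total so every map sums to 1.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2 or len(points) == 0:
        raise ValueError("points must be a non-empty (n, 2) array")
    gx, gy = atlas_grid(atlas, grid_size)
    if bandwidth == "scott":
        hx = _scott_bandwidth(points[:, 0], gx[-1] - gx[0])
        hy = _scott_bandwidth(points[:, 1], gy[-1] - gy[0])
    else:
        hx, hy = bandwidth
    # mass[i, j] = sum_p exp(-((gx_i - x_p)/hx)^2 / 2) * exp(-((gy_j - y_p)/hy)^2 / 2)
    ax = np.exp(-0.5 * ((gx[:, None] - points[None, :, 0]) / hx) ** 2)
    ay = np.exp(-0.5 * ((gy[:, None] - points[None, :, 1]) / hy) ** 2)
    mass = ax @ ay.T
    total = mass.sum()
    if total == 0:
        raise ValueError("all density mass fell outside the grid")
    return DensityMap(grid_x=gx, grid_y=gy, mass=mass / total,
                      bandwidth=(hx, hy), sample_id=sample_id)


def density_difference(map_a: DensityMap, map_b: DensityMap) -> np.ndarray:
    """Signed per-node difference a - b; sums to ~0 since both sum to 1."""
    if not map_a.same_grid(map_b):
        raise ValueError("density maps must share an identical grid")
    return map_a.mass - map_b.mass


def territory_mask(
    atlas: ReferenceAtlas, labels: set[str] | frozenset[str],
    grid_x: np.ndarray, grid_y: np.ndarray,
) -> np.ndarray:
    """Boolean (G, G) mask of grid nodes whose nearest reference cell carries
    one of ``labels`` — the reference territory of those cell types."""
    tree = cKDTree(atlas.layout2d)
    xx, yy = np.meshgrid(grid_x, grid_y, indexing="ij")
    nodes = np.column_stack([xx.ravel(), yy.ravel()])
    _, nearest = tree.query(nodes)
    in_set = np.isin(atlas.cell_labels[nearest], sorted(labels))
    return in_set.reshape(len(grid_x), len(grid_y))


def save_density_tsv(dm: DensityMap, path) -> None:
    header = (f"sample_id={dm.sample_id} bandwidth={dm.bandwidth[0]:.17g},"
              f"{dm.bandwidth[1]:.17g}\n"
              f"x={dm.grid_x[0]:.17g}:{dm.grid_x[-1]:.17g}:{len(dm.grid_x)} "
              f"y={dm.grid_y[0]:.17g}:{dm.grid_y[-1]:.17g}:{len(dm.grid_y)}")
    np.savetxt(path, dm.mass, fmt="%.17g", delimiter="\t", header=header)


def render_png(dm: DensityMap, path, atlas: ReferenceAtlas | None = None) -> None:
    """Optional heat rendering of a density map (thin layer over the grid)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.pcolormesh(dm.grid_x, dm.grid_y, dm.mass.T, shading="auto", cmap="magma")
    if atlas is not None:
        ax.scatter(atlas.layout2d[:, 0], atlas.layout2d[:, 1],
                   s=1, c="grey", alpha=0.2, linewidths=0)
    ax.set_title(dm.sample_id)
    ax.set_xlabel("layout 1")
    ax.set_ylabel("layout 2")
    fig.savefig(path, dpi=150)
    plt.close(fig)
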