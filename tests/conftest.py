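"""Shared fixtures: the synthetic demo atlas and annotated preset samples.

Both are expensive enough to build once per session; every value derived
from them is deterministic given the seeds fixed here.
"""

from __future__ import annotations

import numpy as np
import pytest

import marrowmap as mm

REF_SEED = 7
PRESET_SEED = 11
PRESET_N_CELLS = 5000

#: QC thresholds matched to the generator's 1,500-gene panel (~150 detected
#: genes per cell), replacing the real-data default of 200.
SYNTH_QC = {"min_genes_per_cell": 50, "max_mito_fraction": 1.0,
            "min_cells_per_gene": 1}


@pytest.fixture(scope="session")
def ref_fixture():
    return mm.make_reference_fixture(seed=REF_SEED)


@pytest.fixture(scope="session")
def atlas(ref_fixture):
    return ref_fixture.atlas


@pytest.fixture(scope="session")
def preset_annotations(atlas):
    """Annotated 5,000-cell samples for the three preset phenotypes, with
    their generator truths."""
    out = {}
    for preset in ("healthy", "MDS_high", "MDS_low"):
        cm, truth = mm.simulate_preset(preset, n_cells=PRESET_N_CELLS,
                                       seed=PRESET_SEED)
        ann = mm.annotate_sample(cm, atlas, group="other", k=15,
                                 qc_params=SYNTH_QC)
        out[preset] = (ann, truth)
    return out


@pytest.fixture()
def tiny_atlas():
    """A hand-built 4-cell atlas in a 2-PC space (identity loadings) for
    closed-form neighbor tests."""
    taxonomy = mm.default_taxonomy()
    return mm.ReferenceAtlas(
        taxonomy=taxonomy,
        cell_labels=np.array(["T", "B", "T", "NK"]),
        hvg=["G1", "G2"],
        gene_means=np.zeros(2),
        gene_sds=np.ones(2),
        pc_loadings=np.eye(2),
        pc_coords=np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0], [4.0, 4.0]]),
        layout2d=np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0], [4.0, 4.0]]),
    )
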