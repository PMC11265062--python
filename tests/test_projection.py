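"""Query projection, kNN label transfer and layout imputation."""

import numpy as np
import pytest
import scipy.sparse as sp

import marrowmap as mm
from marrowmap.projection import FeatureMismatchError

from conftest import SYNTH_QC


class TestAlignFeatures:
    def test_scrambled_gene_order_is_identity(self, ref_fixture):
        atlas = ref_fixture.atlas
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(ref_fixture.counts.genes))
        scrambled_genes = [ref_fixture.counts.genes[i] for i in perm]
        scrambled = sp.csr_matrix(ref_fixture.norm)[perm]
        a, miss_a = mm.align_features(scrambled, scrambled_genes, atlas)
        b, miss_b = mm.align_features(ref_fixture.norm,
                                      ref_fixture.counts.genes, atlas)
        np.testing.assert_array_equal(a, b)
        assert miss_a == miss_b == 0.0

    def test_one_missing_hvg_zero_filled(self, ref_fixture):
        atlas = ref_fixture.atlas
        drop = atlas.hvg[3]
        keep = [i for i, g in enumerate(ref_fixture.counts.genes) if g != drop]
        genes = [ref_fixture.counts.genes[i] for i in keep]
        aligned, missing = mm.align_features(
            sp.csr_matrix(ref_fixture.norm)[keep], genes, atlas)
        assert missing == pytest.approx(1 / len(atlas.hvg))
        assert not aligned[:, 3].any()

    def test_majority_missing_aborts(self, tiny_atlas):
        with pytest.raises(FeatureMismatchError, match="feature mismatch"):
            mm.align_features(sp.csr_matrix(np.ones((1, 3))), ["other"],
                              tiny_atlas)


class TestProjectCells:
    def test_reference_self_consistency(self, ref_fixture):
        atlas = ref_fixture.atlas
        aligned, _ = mm.align_features(ref_fixture.norm,
                                       ref_fixture.counts.genes, atlas)
        pc = mm.project_cells(aligned, atlas)
        assert np.abs(pc - atlas.pc_coords).max() < 1e-6

    def test_all_zero_cell_is_fixed_vector(self, ref_fixture):
        atlas = ref_fixture.atlas
        pc = mm.project_cells(np.zeros((1, len(atlas.hvg))), atlas)
        expected = np.clip(-atlas.gene_means / atlas.gene_sds,
                           -atlas.clip_value, atlas.clip_value) @ atlas.pc_loadings
        np.testing.assert_allclose(pc[0], expected)

    def test_matches_independent_matrix_algebra(self, ref_fixture):
        atlas = ref_fixture.atlas
        rng = np.random.default_rng(4)
        Q = rng.gamma(1.0, 1.0, size=(10, len(atlas.hvg)))
        pc = mm.project_cells(Q, atlas)
        Z = np.minimum(np.maximum((Q - atlas.gene_means) / atlas.gene_sds,
                                  -10.0), 10.0)
        np.testing.assert_allclose(pc, Z @ atlas.pc_loadings, rtol=1e-10)


class TestTransferLabels:
    def test_reference_cell_with_k1_returns_own_label(self, tiny_atlas):
        labels, conf = mm.transfer_labels(tiny_atlas.pc_coords, tiny_atlas, k=1)
        assert list(labels) == list(tiny_atlas.cell_labels)
        assert (conf == 1.0).all()

    def test_tie_broken_by_nearest_neighbor(self, tiny_atlas):
        # query at (0.3, 0): nearest = T at (0,0), then B at (1,0)
        labels, conf = mm.transfer_labels(np.array([[0.3, 0.0]]), tiny_atlas, k=2)
        assert labels[0] == "T"
        assert conf[0] == 0.5

    def test_separated_five_type_query_recovers_95pct(self, atlas):
        taxonomy = atlas.taxonomy
        comp = {l: 0.0 for l in taxonomy.labels}
        comp.update({"HSPC": 0.2, "GMP": 0.2, "Neutrophil": 0.2,
                     "T": 0.2, "B": 0.2})
        # well-separated centroids: markers one log-unit stronger than the
        # generator default
        cm, truth = mm.simulate_sample(mm.GeneratorSpec(
            composition=comp, n_cells=1000, seed=21, marker_log_fc=3.0))
        ann = mm.annotate_sample(cm, atlas, k=15, qc_params=SYNTH_QC)
        kept = [int(c.split("C")[-1]) for c in ann.cell_ids]
        assert (ann.label == truth[kept]).mean() >= 0.95

    def test_invariant_to_query_order(self, tiny_atlas):
        rng = np.random.default_rng(8)
        q = rng.normal(size=(40, 2))
        labels, conf = mm.transfer_labels(q, tiny_atlas, k=3)
        perm = rng.permutation(40)
        labels_p, conf_p = mm.transfer_labels(q[perm], tiny_atlas, k=3)
        assert np.array_equal(labels_p, labels[perm])
        assert np.array_equal(conf_p, conf[perm])

    def test_confidence_is_valid_vote_fraction(self, tiny_atlas):
        rng = np.random.default_rng(9)
        q = rng.normal(size=(50, 2), scale=3)
        for k in (1, 2, 3, 4):
            _, conf = mm.transfer_labels(q, tiny_atlas, k=k)
            votes = conf * k
            np.testing.assert_allclose(votes, np.round(votes), atol=1e-12)
            assert votes.min() >= 1 and votes.max() <= k

    @pytest.mark.parametrize("k", [0, -3])
    def test_nonpositive_k_rejected(self, tiny_atlas, k):
        with pytest.raises(ValueError, match="k must be"):
            mm.transfer_labels(np.zeros((1, 2)), tiny_atlas, k=k)


class TestImputeLayout:
    def test_reference_cell_recovers_own_layout(self, tiny_atlas):
        lay = mm.impute_layout(tiny_atlas.pc_coords, tiny_atlas, k=3)
        assert np.abs(lay - tiny_atlas.layout2d).max() < 1e-6

    def test_two_equidistant_neighbors_give_midpoint(self, tiny_atlas):
        # (0.5, 0) is equidistant from T at (0,0) and B at (1,0)
        lay = mm.impute_layout(np.array([[0.5, 0.0]]), tiny_atlas, k=2)
        np.testing.assert_allclose(lay[0], [0.5, 0.0], atol=1e-9)

    def test_result_inside_neighbor_convex_hull(self, atlas):
        from scipy.spatial import Delaunay
        from sklearn.neighbors import NearestNeighbors

        rng = np.random.default_rng(12)
        q = rng.normal(size=(20, atlas.n_pcs), scale=5)
        k = 15
        lay = mm.impute_layout(q, atlas, k=k)
        nn = NearestNeighbors(n_neighbors=k).fit(atlas.pc_coords)
        _, idx = nn.kneighbors(q)
        for i in range(len(q)):
            hull = Delaunay(atlas.layout2d[idx[i]])
            assert hull.find_simplex(lay[i], tol=1e-9) >= 0


class TestAnnotateSample:
    def test_deterministic_end_to_end(self, atlas):
        cm, _ = mm.simulate_preset("healthy", n_cells=600, seed=33)
        a = mm.annotate_sample(cm, atlas, k=15, qc_params=SYNTH_QC)
        b = mm.annotate_sample(cm, atlas, k=15, qc_params=SYNTH_QC)
        assert np.array_equal(a.label, b.label)
        assert np.array_equal(a.pc_coords, b.pc_coords)
        assert np.array_equal(a.layout2d, b.layout2d)
        assert a.cell_ids == b.cell_ids

    def test_self_annotation_k1_reproduces_reference(self, ref_fixture):
        atlas = ref_fixture.atlas
        ann = mm.annotate_sample(ref_fixture.counts, atlas, k=1,
                                 qc_params={"min_genes_per_cell": 0,
                                            "max_mito_fraction": 1.0,
                                            "min_cells_per_gene": 0})
        assert (ann.label == ref_fixture.labels).all()
        assert np.abs(ann.layout2d - atlas.layout2d).max() < 1e-6

    def test_preset_ordering_mature_myeloid(self, preset_annotations):
        tax = mm.default_taxonomy()
        mature = {}
        for preset, (ann, _) in preset_annotations.items():
            frac = mm.fractions(list(ann.label), tax)
            mature[preset] = mm.mature_myeloid_fraction(frac, tax)
        assert mature["MDS_high"] < mature["MDS_low"] < mature["healthy"]
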