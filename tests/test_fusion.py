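import numpy as np
import pytest

from mirdap.errors import ConfigurationError, DataError
from mirdap.fusion import (assemble_dataset, build_feature_vector,
                           feature_width, fuse_disease_similarity,
                           fuse_mirna_similarity, sample_negatives)
from mirdap.io_formats import AssociationSet, NamedMatrix


def square(labels, values):
    return NamedMatrix(list(labels), list(labels), np.asarray(values, float))


class TestDiseaseFusion:
    def setup_method(self):
        self.gd = square(["a", "b"], [[1.0, 0.1353], [0.1353, 1.0]])

    def test_semantic_average_when_both_covered(self):
        sv1 = square(["a", "b"], [[1.0, 0.6], [0.6, 1.0]])
        sv2 = square(["a", "b"], [[1.2, 0.4], [0.4, 1.2]])
        dsim, prov = fuse_disease_similarity(sv1, sv2, self.gd,
                                             {"a": True, "b": True})
        assert dsim.loc("a", "b") == pytest.approx(0.5)
        assert dsim.loc("a", "a") == pytest.approx((1.0 + 1.2) / 2)
        assert (prov == "semantic").all()

    def test_kernel_fallback_when_uncovered(self):
        sv1 = square(["a"], [[1.0]])
        sv2 = square(["a"], [[1.5]])
        dsim, prov = fuse_disease_similarity(sv1, sv2, self.gd,
                                             {"a": True, "b": False})
        assert dsim.loc("a", "b") == pytest.approx(0.1353)
        assert prov[0, 1] == "gip" and prov[0, 0] == "semantic"

    def test_unknown_flagged_disease_rejected(self):
        sv1 = square(["a"], [[1.0]])
        with pytest.raises(ConfigurationError):
            fuse_disease_similarity(sv1, sv1, self.gd,
                                    {"a": True, "zzz": True})


class TestMirnaFusion:
    def setup_method(self):
        self.gr = square(["m1", "m2", "m3"],
                         [[1, 0.9, 0.3], [0.9, 1, 0.2], [0.3, 0.2, 1]])

    def test_functional_when_both_present(self):
        rf = square(["m1", "m2"], [[1, 0.8], [0.8, 1]])
        rsim, prov = fuse_mirna_similarity(rf, self.gr, {"m1", "m2"})
        assert rsim.loc("m1", "m2") == pytest.approx(0.8)
        assert prov[0, 1] == "functional"

    def test_kernel_when_one_absent(self):
        rf = square(["m1", "m2"], [[1, 0.8], [0.8, 1]])
        rsim, prov = fuse_mirna_similarity(rf, self.gr, {"m1", "m2"})
        assert rsim.loc("m1", "m3") == pytest.approx(0.3)
        assert prov[0, 2] == "gip"

    def test_full_coverage_reproduces_functional(self):
        vals = np.array([[1, 0.8, 0.5], [0.8, 1, 0.4], [0.5, 0.4, 1]])
        rf = square(["m1", "m2", "m3"], vals)
        rsim, _ = fuse_mirna_similarity(rf, self.gr, {"m1", "m2", "m3"})
        np.testing.assert_allclose(rsim.values, vals)

    def test_no_functional_matrix_uses_kernel_everywhere(self):
        rsim, prov = fuse_mirna_similarity(None, self.gr, None)
        np.testing.assert_allclose(rsim.values, self.gr.values)
        assert (prov == "gip").all()


class TestFeatureVectors:
    def setup_method(self):
        self.dsim = square(["d1", "d2", "d3"], np.eye(3))
        self.rsim = square(["m1", "m2", "m3", "m4"], np.eye(4))
        self.rseq = NamedMatrix(["m1", "m2", "m3", "m4"],
                                [f"dim{i}" for i in range(64)],
                                np.arange(4 * 64).reshape(4, 64) / 100.0)

    def test_toy_width(self):
        fv = build_feature_vector("d1", "m2", self.dsim, self.rsim, self.rseq)
        assert fv.shape == (3 + 4 + 64,)

    def test_full_scale_width_formula(self):
        assert feature_width("full", 850, 1057, 64) == 1971
        assert feature_width("DescSeq", 3, 4, 64) == 67
        assert feature_width("DescSim", 3, 4, 64) == 7

    def test_concatenation_order(self):
        fv = build_feature_vector("d2", "m3", self.dsim, self.rsim, self.rseq)
        np.testing.assert_array_equal(fv[:3], [0, 1, 0])          # DSim row
        np.testing.assert_array_equal(fv[3:7], [0, 0, 1, 0])      # RSim col
        np.testing.assert_array_equal(fv[7:], self.rseq.values[2])

    def test_identical_mirna_features_give_identical_vectors(self):
        rsim = square(["m1", "m2"], [[1, 1], [1, 1]])
        rseq = NamedMatrix(["m1", "m2"], ["dim0"], np.array([[0.5], [0.5]]))
        a = build_feature_vector("d1", "m1", self.dsim, rsim, rseq)
        b = build_feature_vector("d1", "m2", self.dsim, rsim, rseq)
        np.testing.assert_array_equal(a, b)


class TestNegativeSampling:
    def test_forced_complement(self):
        a = AssociationSet(["d1", "d2"], ["m1", "m2"],
                           np.array([[1, 0], [0, 1]]))
        negs = sample_negatives(a, 2, seed=0)
        assert sorted(negs) == [("d1", "m2"), ("d2", "m1")]

    def test_count_too_large_rejected(self):
        a = AssociationSet(["d1"], ["m1", "m2"], np.array([[1, 0]]))
        with pytest.raises(ConfigurationError):
            sample_negatives(a, 2, seed=0)

    @pytest.mark.parametrize("seed", range(25))
    def test_disjoint_from_positives(self, seed, rng):
        ad = np.random.default_rng(seed).integers(0, 2, size=(6, 9))
        a = AssociationSet([f"d{i}" for i in range(6)],
                           [f"m{j}" for j in range(9)], ad)
        pos = set(a.positive_pairs())
        count = min(len(pos), int(ad.size - ad.sum()))
        if count == 0:
            pytest.skip("degenerate draw")
        negs = sample_negatives(a, count, seed=seed)
        assert len(negs) == len(set(negs)) == count
        assert not (set(negs) & pos)

    def test_seeded_reproducibility(self):
        a = AssociationSet([f"d{i}" for i in range(5)],
                           [f"m{j}" for j in range(8)],
                           np.zeros((5, 8), dtype=int))
        assert sample_negatives(a, 10, seed=3) == sample_negatives(a, 10, seed=3)


class TestAssembly:
    def setup_method(self):
        n_d, n_m = 4, 5
        self.dsim = square([f"d{i}" for i in range(n_d)], np.eye(n_d))
        self.rsim = square([f"m{j}" for j in range(n_m)], np.eye(n_m))
        self.rseq = NamedMatrix([f"m{j}" for j in range(n_m)],
                                [f"dim{i}" for i in range(8)],
                                np.ones((n_m, 8)))
        self.pos = [(f"d{i % 4}", f"m{i % 5}") for i in range(10)]
        self.pos = sorted(set(self.pos))
        self.neg = [("d0", "m1"), ("d0", "m2"), ("d2", "m4")]

    def test_labels_and_counts(self):
        t = assemble_dataset(self.pos, self.neg, self.dsim, self.rsim,
                             self.rseq, seed=1)
        assert len(t.pairs) == len(self.pos) + len(self.neg)
        assert t.labels.sum() == len(self.pos)
        assert t.feature_width == 4 + 5 + 8

    def test_overlap_rejected(self):
        with pytest.raises(DataError):
            assemble_dataset(self.pos, [self.pos[0]], self.dsim, self.rsim,
                             self.rseq)

    def test_ablation_widths(self):
        seq = assemble_dataset(self.pos, self.neg, self.dsim, self.rsim,
                               self.rseq, mode="DescSeq")
        sim = assemble_dataset(self.pos, self.neg, self.dsim, self.rsim,
                               self.rseq, mode="DescSim")
        assert seq.feature_width == 4 + 8
        assert sim.feature_width == 4 + 5

    def test_shuffle_is_seeded(self):
        t1 = assemble_dataset(self.pos, self.neg, self.dsim, self.rsim,
                              self.rseq, seed=9)
        t2 = assemble_dataset(self.pos, self.neg, self.dsim, self.rsim,
                              self.rseq, seed=9)
        assert t1.pairs == t2.pairs
        np.testing.assert_array_equal(t1.features, t2.features)

    def test_optional_reduction_stage(self):
        t = assemble_dataset(self.pos, self.neg, self.dsim, self.rsim,
                             self.rseq, seed=1, reduce_to=3)
        assert t.features.shape[1] == 3
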