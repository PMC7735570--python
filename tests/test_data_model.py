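import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anovahd import (
    FeatureMatrix,
    GenotypeMatrix,
    align_samples,
    center_scale_columns,
    ld_prune_adjacent,
    maf_filter,
)
from anovahd.exceptions import (
    DuplicateIds,
    MissingValues,
    SampleMismatch,
    ZeroVarianceColumn,
)


class TestFeatureMatrix:
    def test_missing_values_rejected_with_coordinates(self):
        vals = np.ones((3, 2))
        vals[1, 1] = np.nan
        with pytest.raises(MissingValues) as exc:
            FeatureMatrix(vals, ["a", "b", "c"], ["f1", "f2"])
        assert exc.value.coordinates == [("b", "f2")]

    def test_duplicate_ids_rejected(self):
        with pytest.raises(DuplicateIds):
            FeatureMatrix(np.ones((3, 2)), ["a", "a", "c"], ["f1", "f2"])

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            FeatureMatrix(np.ones((2, 2)))

    def test_genotype_codes_validated(self):
        with pytest.raises(ValueError):
            GenotypeMatrix(np.array([[0, 3], [1, 1], [2, 0]]), ploidy=2)

    def test_genotype_maf_recomputable_from_values(self):
        vals = np.array([[0, 2, 1], [0, 2, 1], [0, 0, 1], [0, 0, 1]], dtype=float)
        G = GenotypeMatrix(vals, ploidy=2)
        freq = vals.mean(axis=0) / 2
        np.testing.assert_allclose(G.maf, np.minimum(freq, 1 - freq))


class TestCenterScale:
    def test_constant_column_raises_and_names_feature(self):
        M = FeatureMatrix(np.column_stack([np.ones(4), np.arange(4.0)]),
                          feature_ids=["const", "ramp"])
        for mode in ("unit_variance", "span_scaled"):
            with pytest.raises(ZeroVarianceColumn) as exc:
                center_scale_columns(M, mode)
            assert exc.value.feature_id == "const"

    def test_span_scaled_orthogonal_columns_kernel_diag(self):
        # 4x2 orthogonal centered columns: span scaling forces per-column
        # (population) variance 1/2 and mean kernel diagonal exactly 1
        M = FeatureMatrix(np.array([[1, 1], [1, -1], [-1, 1], [-1, -1.0]]))
        V = center_scale_columns(M, "span_scaled").values
        np.testing.assert_allclose(V.var(axis=0), 0.5, atol=1e-12)
        assert abs(np.mean(np.diag(V @ V.T)) - 1.0) < 1e-12

    def test_unit_variance_matches_direct_recomputation(self):
        rng = np.random.default_rng(42)
        M = FeatureMatrix(rng.standard_normal((10, 4)))
        V = center_scale_columns(M, "unit_variance").values
        assert np.abs(V.mean(axis=0)).max() < 1e-10
        assert np.abs(V.std(axis=0, ddof=1) - 1.0).max() < 1e-8

    @pytest.mark.parametrize("mode", ["unit_variance", "span_scaled"])
    def test_idempotent_per_mode(self, mode):
        rng = np.random.default_rng(7)
        M = FeatureMatrix(rng.standard_normal((9, 5)) * 3 + 1)
        once = center_scale_columns(M, mode)
        twice = center_scale_columns(once, mode)
        assert np.abs(twice.values - once.values).max() < 1e-10

    def test_original_unmodified(self):
        rng = np.random.default_rng(1)
        vals = rng.standard_normal((6, 3))
        M = FeatureMatrix(vals.copy())
        center_scale_columns(M, "unit_variance")
        np.testing.assert_array_equal(M.values, vals)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        n=st.integers(3, 30),
        p=st.integers(1, 20),
    )
    def test_span_scaled_mean_kernel_diag_is_one(self, seed, n, p):
        rng = np.random.default_rng(seed)
        vals = rng.standard_normal((n, p)) * rng.uniform(0.1, 10, size=p)
        V = center_scale_columns(FeatureMatrix(vals), "span_scaled").values
        assert abs(np.mean(np.sum(V * V, axis=1)) - 1.0) < 1e-8


class TestGenotypeQC:
    def _toy(self):
        # hand-computed allele frequencies: columns at maf 0.0, 0.25, 0.5
        vals = np.array(
            [
                [0, 1, 2],
                [0, 0, 2],
                [0, 1, 2],
                [0, 0, 0],
                [0, 1, 0],
                [0, 0, 0],
            ],
            dtype=float,
        )
        return GenotypeMatrix(vals, feature_ids=["mono", "rare", "common"], ploidy=2)

    def test_monomorphic_removed_at_any_positive_threshold(self):
        G = self._toy()
        kept, removed = maf_filter(G, 1e-6)
        assert "mono" not in kept.feature_ids and removed == 1

    def test_paper_default_threshold_keeps_maf_above(self):
        vals = np.zeros((100, 1))
        vals[:2, 0] = 1.0  # maf 0.01 at ploidy 1
        G = GenotypeMatrix(vals, ploidy=1)
        kept, removed = maf_filter(G, 0.005)
        assert kept.n_features == 1 and removed == 0

    def test_hand_computed_mafs_filtered(self):
        kept, removed = maf_filter(self._toy(), 0.1)
        assert kept.feature_ids == ["rare", "common"]
        assert removed == 1

    def test_filter_preserves_column_order(self):
        kept, _ = maf_filter(self._toy(), 0.0)
        assert kept.feature_ids == ["mono", "rare", "common"]

    def test_ld_prune_drops_duplicate_adjacent(self):
        col = np.array([0, 1, 1, 0, 1, 0, 0, 1.0])
        other = np.array([1, 1, 0, 0, 1, 0, 1, 0.0])
        G = GenotypeMatrix(np.column_stack([col, col, other]),
                          feature_ids=["a", "b", "c"], ploidy=1)
        pruned = ld_prune_adjacent(G, 0.99)
        assert pruned.feature_ids == ["a", "c"]

    def test_ld_prune_compares_to_last_retained(self):
        # adjacent r^2: (c1,c2) = 0.5ish < 0.99 -> keep c2; (c2,c3) = 1 -> drop
        rng = np.random.default_rng(0)
        c1 = (rng.random(8) < 0.5).astype(float)
        c2 = c1.copy()
        c2[:2] = 1 - c2[:2]  # imperfect copy of c1
        G = GenotypeMatrix(np.column_stack([c1, c2, c2]),
                          feature_ids=["a", "b", "c"], ploidy=1)
        r2_ab = np.corrcoef(c1, c2)[0, 1] ** 2
        assert r2_ab < 0.99
        pruned = ld_prune_adjacent(G, 0.99)
        assert pruned.feature_ids == ["a", "b"]

    def test_ld_prune_constant_column_raises(self):
        G = self._toy()
        with pytest.raises(ZeroVarianceColumn):
            ld_prune_adjacent(G, 0.99)


class TestAlignment:
    def test_mismatched_sets_error_without_allow_subset(self):
        A = FeatureMatrix(np.ones((3, 1)) * np.arange(3)[:, None], ["a", "b", "c"])
        B = FeatureMatrix(np.ones((3, 1)), ["a", "b", "d"])
        with pytest.raises(SampleMismatch):
            align_samples(A, B)

    def test_intersection_ordered_by_x(self):
        rng = np.random.default_rng(2)
        A = FeatureMatrix(rng.standard_normal((4, 2)), ["d", "a", "c", "b"])
        B = FeatureMatrix(rng.standard_normal((4, 2)), ["a", "b", "c", "x"])
        Xa, Wb = align_samples(A, B, allow_subset=True)
        assert Xa.sample_ids == Wb.sample_ids == ["a", "c", "b"]
        np.testing.assert_array_equal(Xa.values, A.values[[1, 2, 3]])
        np.testing.assert_array_equal(Wb.values, B.values[[0, 2, 1]])
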