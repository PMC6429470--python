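import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp

from gcgrloc.fusion import (
    ComplexFeature,
    DistanceModel,
    fit_distance_model,
    parallel_combine,
    predict_distance,
    unitary_distance,
    unitary_norm,
)

real_vectors = hnp.arrays(
    dtype=float,
    shape=st.integers(min_value=1, max_value=8),
    elements=st.floats(min_value=-100, max_value=100, allow_nan=False),
)


class TestParallelCombine:
    def test_equal_dimensions_no_padding(self):
        z = parallel_combine([1.0, 2.0], [3.0, 4.0])
        np.testing.assert_array_equal(z.z, [1 + 3j, 2 + 4j])

    def test_ratio_rule_pads_with_xbar_over_ybar(self):
        z = parallel_combine([1.5, 3.0], [7.0, 8.0, 9.0], pad_values=(1.5, 3.0), rule="ratio")
        assert len(z) == 3
        np.testing.assert_allclose(z.real_part, [1.5, 3.0, 0.5])
        np.testing.assert_array_equal(z.imag_part, [7.0, 8.0, 9.0])

    def test_alternate_rule_cycles_xbar_ybar(self):
        z = parallel_combine([1.0], [0.0] * 4, pad_values=(10.0, 20.0), rule="alternate")
        np.testing.assert_array_equal(z.real_part, [1.0, 10.0, 20.0, 10.0])

    def test_higher_dimensional_vector_untouched(self):
        v = [5.0, 6.0, 7.0, 8.0]
        z = parallel_combine([1.0], v, pad_values=(2.0, 4.0))
        np.testing.assert_array_equal(z.imag_part, v)

    def test_ratio_with_zero_ybar_rejected(self):
        with pytest.raises(ZeroDivisionError):
            parallel_combine([1.0], [1.0, 2.0], pad_values=(1.0, 0.0), rule="ratio")

    def test_padding_metadata_recorded(self):
        z = parallel_combine([1.0, 2.0], [1.0, 2.0, 3.0], pad_values=(1.0, 2.0))
        assert z.padded_from["dim_u"] == 2
        assert z.padded_from["dim_v"] == 3


class TestUnitaryNorm:
    def test_three_four_five(self):
        assert unitary_norm(np.array([3 + 4j])) == pytest.approx(5.0)

    def test_zero_vector(self):
        assert unitary_norm(np.zeros(4, dtype=complex)) == 0.0

    @given(u=real_vectors)
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_equals_euclidean_norm_of_stacked_parts(self, u):
        v = u[::-1].copy()
        z = u + 1j * v
        stacked = np.concatenate([u, v])
        assert unitary_norm(z) == pytest.approx(float(np.linalg.norm(stacked)), abs=1e-12)


class TestUnitaryDistance:
    def test_identity_of_indiscernibles(self):
        z = np.array([1 + 2j, 3 - 1j])
        assert unitary_distance(z, z) == 0.0

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            unitary_distance(np.zeros(2, dtype=complex), np.zeros(3, dtype=complex))

    @given(u=real_vectors, seed=st.integers(0, 2**16))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_metric_axioms(self, u, seed):
        rng = np.random.default_rng(seed)
        n = len(u)
        z1 = u + 1j * rng.normal(size=n)
        z2 = rng.normal(size=n) + 1j * rng.normal(size=n)
        z3 = rng.normal(size=n) + 1j * rng.normal(size=n)
        d12 = unitary_distance(z1, z2)
        d21 = unitary_distance(z2, z1)
        assert d12 >= 0
        assert d12 == pytest.approx(d21, abs=1e-12)
        assert unitary_distance(z1, z3) <= d12 + unitary_distance(z2, z3) + 1e-12

    def test_symmetric_in_real_imag_swap(self):
        # |a + bi| = |b + ai|: which view is real vs imaginary cannot
        # change any distance.
        rng = np.random.default_rng(7)
        u1, v1 = rng.normal(size=3), rng.normal(size=3)
        u2, v2 = rng.normal(size=3), rng.normal(size=3)
        d_uv = unitary_distance(u1 + 1j * v1, u2 + 1j * v2)
        d_vu = unitary_distance(v1 + 1j * u1, v2 + 1j * u2)
        assert d_uv == pytest.approx(d_vu, abs=1e-12)


def _features(arrays):
    return [ComplexFeature(z=np.asarray(a, dtype=complex)) for a in arrays]


class TestDistanceModel:
    def test_single_sample_centroid_is_the_sample(self):
        feats = _features([[1 + 1j, 2], [5 + 3j, 4]])
        model = fit_distance_model(feats, ["a", "b"])
        np.testing.assert_array_equal(model.templates["a"], feats[0].z)

    def test_three_sample_centroid_hand_mean(self):
        feats = _features([[0 + 0j], [3 + 3j], [6 + 0j]])
        model = fit_distance_model(feats, ["a", "a", "a"])
        np.testing.assert_allclose(model.templates["a"], [3 + 1j])

    def test_query_at_centroid_returns_its_class(self):
        feats = _features([[0 + 0j], [10 + 0j]])
        model = fit_distance_model(feats, ["a", "b"])
        assert predict_distance(model, np.array([10 + 0j])) == "b"

    def test_equidistant_tie_goes_to_first_class(self):
        feats = _features([[0 + 0j], [2 + 0j]])
        model = fit_distance_model(feats, ["a", "b"])
        assert predict_distance(model, np.array([1 + 0j])) == "a"

    def test_neighbor_mode_stores_and_uses_all_samples(self):
        feats = _features([[0 + 0j], [4 + 0j], [10 + 0j]])
        model = fit_distance_model(feats, ["a", "a", "b"], mode="neighbor")
        assert len(model.samples) == 3
        assert predict_distance(model, np.array([5 + 0j])) == "a"

    def test_empty_class_rejected(self):
        feats = _features([[1 + 0j]])
        with pytest.raises(ValueError, match="no training samples"):
            fit_distance_model(feats, ["a"], classes=["a", "b"])

    def test_real_only_features_reduce_to_euclidean_nearest_centroid(self, rng):
        # With zero imaginary parts the unitary model must agree with a
        # plain real-space nearest-centroid oracle.
        X = rng.normal(size=(20, 4))
        labels = ["a" if i < 10 else "b" for i in range(20)]
        feats = _features([row.astype(complex) for row in X])
        model = fit_distance_model(feats, labels)
        centroid_a, centroid_b = X[:10].mean(axis=0), X[10:].mean(axis=0)
        for _ in range(20):
            q = rng.normal(size=4)
            expected = "a" if np.linalg.norm(q - centroid_a) < np.linalg.norm(q - centroid_b) else "b"
            assert predict_distance(model, q.astype(complex)) == expected

    def test_translation_invariance_of_predictions(self, rng):
        X = rng.normal(size=(10, 3)) + 1j * rng.normal(size=(10, 3))
        labels = ["a"] * 5 + ["b"] * 5
        shift = (2.5 - 1.5j) * np.ones(3)
        model = fit_distance_model(_features(X), labels)
        shifted = fit_distance_model(_features(X + shift), labels)
        for _ in range(10):
            q = rng.normal(size=3) + 1j * rng.normal(size=3)
            assert predict_distance(model, q) == predict_distance(shifted, q + shift)

    def test_json_round_trip(self):
        feats = _features([[1 + 2j, 3 + 4j], [5 + 6j, 7 + 8j]])
        model = fit_distance_model(feats, ["a", "b"])
        restored = DistanceModel.from_json(model.to_json())
        assert restored.classes == model.classes
        for c in model.classes:
            np.testing.assert_array_equal(restored.templates[c], model.templates[c])
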