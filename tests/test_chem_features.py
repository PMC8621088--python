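"""Descriptor computation and the three pair-combination operators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from haini.chem_features import (
    DEFAULT_DESCRIPTOR_NAMES,
    DescriptorVector,
    compute_descriptors,
    concat_features,
    cross_product_features,
    sum_product_features,
)
from haini.errors import DimensionError, SmilesParseError


class TestComputeDescriptors:
    def test_default_panel_length(self):
        vec = compute_descriptors("C")
        assert len(vec) == 60
        assert vec.names == DEFAULT_DESCRIPTOR_NAMES
        assert np.all(np.isfinite(vec.values))

    def test_canonicalization_invariance(self):
        a = compute_descriptors("CCO")
        b = compute_descriptors("OCC")
        np.testing.assert_array_equal(a.values, b.values)

    def test_malformed_smiles_raises(self):
        with pytest.raises(SmilesParseError) as err:
            compute_descriptors("C((")
        assert "C((" in str(err.value)

    def test_named_mrvsa_bins_present(self):
        assert "MRVSA2" in DEFAULT_DESCRIPTOR_NAMES
        assert "MRVSA6" in DEFAULT_DESCRIPTOR_NAMES


class TestOperators:
    def test_cross_product_hand_example(self, toy_vectors):
        fa, fb = toy_vectors
        fv = cross_product_features(fa, fb)
        # k = (i-1)p + j: row-major, victim index outer
        np.testing.assert_array_equal(fv.values, [10.0, 14.0, 15.0, 21.0])
        assert fv.names == ("A:x*B:x", "A:x*B:y", "A:y*B:x", "A:y*B:y")

    def test_concat_hand_example(self, toy_vectors):
        fa, fb = toy_vectors
        np.testing.assert_array_equal(concat_features(fa, fb).values, [2, 3, 5, 7])

    def test_sum_product_blocked_layout(self, toy_vectors):
        fa, fb = toy_vectors
        # sums block first, then products block
        np.testing.assert_array_equal(
            sum_product_features(fa, fb).values, [7.0, 10.0, 10.0, 21.0])

    def test_zero_annihilation(self, toy_vectors):
        _, fb = toy_vectors
        zero = DescriptorVector("Z", ("x", "y"), np.zeros(2))
        assert not cross_product_features(zero, fb).values.any()
        np.testing.assert_array_equal(
            sum_product_features(zero, zero).values, np.zeros(4))

    def test_concat_of_identical_vector_repeats(self, toy_vectors):
        fa, _ = toy_vectors
        v = concat_features(fa, fa).values
        np.testing.assert_array_equal(v[:2], v[2:])

    def test_length_mismatch_raises(self, toy_vectors):
        fa, _ = toy_vectors
        f3 = DescriptorVector("C", ("x", "y", "z"), np.ones(3))
        for op in (cross_product_features, concat_features, sum_product_features):
            with pytest.raises(DimensionError):
                op(fa, f3)

    def test_real_molecule_feature_counts(self, provider):
        fa = compute_descriptors("CC(=O)Oc1ccccc1C(=O)O", "a", provider)
        fb = compute_descriptors("CCOc1ccc(CC)cc1", "b", provider)
        assert len(cross_product_features(fa, fb)) == 3600
        assert len(concat_features(fa, fb)) == 120
        assert len(sum_product_features(fa, fb)) == 120


vectors = st.integers(1, 5).flatmap(
    lambda p: st.tuples(
        st.lists(st.floats(-50, 50), min_size=p, max_size=p),
        st.lists(st.floats(-50, 50), min_size=p, max_size=p),
    )
)


@settings(derandomize=True, max_examples=50)
@given(vectors)
def test_operators_match_bruteforce(pair):
    """Each operator equals an explicit double/single loop for p <= 5."""
    a, b = pair
    p = len(a)
    names = tuple(f"d{i}" for i in range(p))
    fa = DescriptorVector("A", names, np.array(a))
    fb = DescriptorVector("B", names, np.array(b))

    cross = cross_product_features(fa, fb).values
    expected = [a[i] * b[j] for i in range(p) for j in range(p)]
    np.testing.assert_allclose(cross, expected)

    np.testing.assert_allclose(concat_features(fa, fb).values, list(a) + list(b))
    np.testing.assert_allclose(
        sum_product_features(fa, fb).values,
        [a[i] + b[i] for i in range(p)] + [a[i] * b[i] for i in range(p)])


@settings(derandomize=True, max_examples=50)
@given(vectors)
def test_operator_swap_symmetries(pair):
    """cross(a,b) is the transpose of cross(b,a); sum/product blocks are symmetric."""
    a, b = pair
    p = len(a)
    names = tuple(f"d{i}" for i in range(p))
    fa = DescriptorVector("A", names, np.array(a))
    fb = DescriptorVector("B", names, np.array(b))

    ab = cross_product_features(fa, fb).values.reshape(p, p)
    ba = cross_product_features(fb, fa).values.reshape(p, p)
    np.testing.assert_allclose(ab, ba.T)

    sp_ab = sum_product_features(fa, fb).values
    sp_ba = sum_product_features(fb, fa).values
    np.testing.assert_allclose(sp_ab, sp_ba)
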