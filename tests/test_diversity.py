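"""Diversity and dysbiosis indices: closed forms and structural properties."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from plaquetopics import (
    ValidationError,
    bray_curtis,
    diversity_profiles,
    inverse_simpson,
    mean_bray_curtis,
    richness,
    shannon,
    smdi,
)

count_rows = arrays(
    np.int64, st.integers(2, 12), elements=st.integers(0, 1000)
).filter(lambda a: a.sum() >= 1)


class TestClosedForms:
    @pytest.mark.parametrize(
        "row,expected",
        [([5, 0, 2, 0], 2), ([0, 0], 0), ([1, 1, 1, 1, 1], 5)],
    )
    def test_richness(self, row, expected):
        assert richness(np.array(row)) == expected

    @pytest.mark.parametrize(
        "row,expected",
        [
            ([10, 10, 10, 10], math.log(4)),
            ([42, 0, 0], 0.0),
            ([5, 3, 2], 1.0296530140645737),
        ],
    )
    def test_shannon(self, row, expected):
        assert shannon(np.array(row)) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize(
        "row,expected",
        [([3, 3, 3, 3, 3], 5.0), ([9, 0, 0], 1.0), ([6, 2], 1.6)],
    )
    def test_inverse_simpson(self, row, expected):
        assert inverse_simpson(np.array(row)) == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ([3, 1, 4], [3, 1, 4], 0.0),
            ([5, 0, 0], [0, 2, 3], 1.0),
            ([6, 2], [2, 2], 1 / 3),
        ],
    )
    def test_bray_curtis(self, a, b, expected):
        assert bray_curtis(np.array(a), np.array(b)) == pytest.approx(expected, abs=1e-9)

    def test_smdi_values(self):
        genus = ["d1", "d2", "h1"]
        assert smdi(np.array([5, 5, 10]), genus, ["d1", "d2"], ["h1"], 1e-12) == (
            pytest.approx(0.0, abs=1e-9)
        )
        assert smdi(np.array([100, 0, 10]), genus, ["d1", "d2"], ["h1"], 1e-12) == (
            pytest.approx(1.0, abs=1e-9)
        )
        assert smdi(np.array([0, 0, 99]), genus, ["d1", "d2"], ["h1"], 1.0) == (
            pytest.approx(-2.0, abs=1e-9)
        )

    def test_smdi_list_validation(self):
        with pytest.raises(ValidationError, match="overlap"):
            smdi(np.array([1, 1]), ["a", "b"], ["a"], ["a", "b"])
        with pytest.raises(ValidationError, match="non-empty"):
            smdi(np.array([1, 1]), ["a", "b"], [], ["b"])


class TestProperties:
    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(row=count_rows)
    def test_hill_number_ordering(self, row):
        """exp(Shannon) >= inverse Simpson for every abundance vector."""
        assert math.exp(shannon(row)) >= inverse_simpson(row) - 1e-9

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(row=count_rows, n_zeros=st.integers(1, 5))
    def test_zero_genera_do_not_change_alpha_diversity(self, row, n_zeros):
        padded = np.concatenate([row, np.zeros(n_zeros, dtype=np.int64)])
        assert shannon(padded) == pytest.approx(shannon(row), abs=1e-12)
        assert inverse_simpson(padded) == pytest.approx(inverse_simpson(row), abs=1e-12)
        assert richness(padded) == richness(row)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        a=arrays(np.int64, 6, elements=st.integers(0, 500)),
        b=arrays(np.int64, 6, elements=st.integers(0, 500)),
    )
    def test_bray_curtis_symmetric_and_bounded(self, a, b):
        if a.sum() + b.sum() == 0:
            return
        d = bray_curtis(a, b)
        assert d == pytest.approx(bray_curtis(b, a), abs=1e-12)
        assert -1e-12 <= d <= 1 + 1e-12

    def test_bray_curtis_all_zero_pair_rejected(self):
        with pytest.raises(ValidationError):
            bray_curtis(np.zeros(3), np.zeros(3))


class TestMeanBrayCurtis:
    def test_matches_pairwise_oracle(self, rng):
        counts = rng.integers(0, 50, size=(8, 5))
        counts[:, 0] += 1
        got = mean_bray_curtis(counts)
        for i in range(8):
            expected = np.mean(
                [bray_curtis(counts[i], counts[j]) for j in range(8) if j != i]
            )
            assert got[i] == pytest.approx(expected, abs=1e-12)

    def test_grouping_and_singletons(self, caplog):
        counts = np.array([[5, 0], [5, 0], [1, 9]])
        groups = np.array(["a", "a", "b"])
        with caplog.at_level("WARNING"):
            got = mean_bray_curtis(counts, groups)
        assert got[0] == pytest.approx(0.0)  # identical to its sole comparator
        assert np.isnan(got[2])  # singleton group has no comparator

    def test_comparator_order_irrelevant(self, rng):
        counts = rng.integers(1, 30, size=(6, 4))
        perm = rng.permutation(6)
        assert np.allclose(mean_bray_curtis(counts)[perm], mean_bray_curtis(counts[perm]))


class TestProfiles:
    def test_invariants_on_cohort(self, small_cohort):
        _, dataset, _ = small_cohort
        prof = diversity_profiles(dataset)
        assert len(prof) == dataset.counts.n_samples
        r = prof["richness"].to_numpy()
        assert (r >= 1).all()
        assert (prof["shannon"] <= np.log(np.maximum(r, 1)) + 1e-9).all()
        assert ((prof["inverse_simpson"] >= 1 - 1e-9) & (prof["inverse_simpson"] <= r + 1e-9)).all()
        bc = prof["mean_bray_curtis"].to_numpy()
        assert ((bc >= 0) & (bc <= 1)).all()
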