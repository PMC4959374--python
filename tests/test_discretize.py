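"""Ameva criterion and the two discretization variants.

The exhaustive-enumeration oracle, the textbook chi-square cross-check
and the subset property live here; heavier batch versions of the same
checks run in the acceptance suite.
"""

import itertools
import warnings

import numpy as np
import pytest
from scipy.stats import chi2_contingency

from adlike import ameva_statistic, candidate_cuts, chi2_dependence, discretize
from adlike.discretize import ContingencyTable, FeatureScheme, scheme_contingency
from adlike.errors import ParameterError


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def exhaustive_best_ameva(values, labels, size):
    """Max Ameva over every candidate-cut subset of the given size."""
    cands = candidate_cuts(values, labels)
    best = -np.inf
    for sub in itertools.combinations(cands, size):
        t = scheme_contingency(FeatureScheme(np.asarray(sub)), values, labels)
        best = max(best, ameva_statistic(t))
    return best


def random_tiny_dataset(seed):
    """<= 12 points over <= 4 tied value groups => <= 3 candidate cuts."""
    rng = np.random.default_rng(seed)
    while True:
        n = int(rng.integers(6, 13))
        values = rng.integers(0, 4, n).astype(float)
        labels = rng.integers(0, int(rng.integers(2, 4)), n)
        if len(np.unique(labels)) >= 2 and candidate_cuts(values, labels).size:
            return values, labels


# ---------------------------------------------------------------------------
# The criterion
# ---------------------------------------------------------------------------

class TestAmevaStatistic:
    def test_perfect_diagonal_table(self):
        t = ContingencyTable([[4, 0], [0, 4]])
        assert chi2_dependence(t) == pytest.approx(8.0)
        assert ameva_statistic(t) == pytest.approx(4.0)

    def test_independent_table_is_zero(self):
        t = ContingencyTable([[6, 3], [4, 2], [2, 1]])
        assert ameva_statistic(t) == pytest.approx(0.0, abs=1e-12)

    def test_matches_textbook_chi_square(self, rng):
        """chi2 equals scipy's expected-count statistic on random tables."""
        for _ in range(20):
            counts = rng.integers(1, 20, size=(3, 2))
            t = ContingencyTable(counts)
            ref = chi2_contingency(counts, correction=False).statistic
            assert chi2_dependence(t) == pytest.approx(ref, rel=1e-10)
            assert ameva_statistic(t) == pytest.approx(ref / (3 * 1), rel=1e-10)

    def test_zero_total_class_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="zero total"):
            v = ameva_statistic(ContingencyTable([[4, 0, 1], [1, 0, 4]]))
        assert v == pytest.approx(ameva_statistic(ContingencyTable([[4, 1], [1, 4]])))

    def test_empty_table_rejected(self):
        with pytest.raises(ParameterError):
            ameva_statistic(ContingencyTable([[0, 0]]))


# ---------------------------------------------------------------------------
# Original variant
# ---------------------------------------------------------------------------

class TestOriginalVariant:
    def test_perfectly_separable_single_cut(self):
        scheme, info = discretize(np.array([1.0, 2.0, 3.0, 4.0]), np.array(["A", "A", "B", "B"]))
        np.testing.assert_array_equal(scheme.cuts, [2.5])
        assert scheme.k == 2
        assert info["ameva"] == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_greedy_attains_exhaustive_maximum(self, seed):
        values, labels = random_tiny_dataset(seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scheme, info = discretize(values, labels)
        if scheme.cuts.size == 0:
            return
        assert info["ameva"] == pytest.approx(
            exhaustive_best_ameva(values, labels, scheme.cuts.size), rel=1e-9
        )

    def test_identical_values_single_interval_with_warning(self):
        with pytest.warns(UserWarning, match="single interval"):
            scheme, _ = discretize(np.ones(6), np.array([1, 1, 1, 2, 2, 2]))
        assert scheme.k == 1

    def test_interval_membership_half_open_right(self):
        scheme = FeatureScheme(np.array([1.0, 3.0]))
        np.testing.assert_array_equal(
            scheme.interval_of(np.array([0.5, 1.0, 1.5, 3.0, 3.5])), [0, 0, 1, 1, 2]
        )

    def test_monotone_transform_invariance(self, rng):
        """The Ameva value is order-based: a strictly monotone transform
        leaves it unchanged and maps the cuts accordingly."""
        values = rng.normal(size=40)
        labels = rng.integers(1, 4, size=40)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s1, i1 = discretize(values, labels)
            s2, i2 = discretize(np.exp(values), labels)
        assert i1["ameva"] == pytest.approx(i2["ameva"], rel=1e-9)
        assert s1.k == s2.k
        # membership of every training point is preserved
        np.testing.assert_array_equal(s1.interval_of(values), s2.interval_of(np.exp(values)))

    def test_relabeling_invariance(self, rng):
        values = rng.normal(size=40)
        labels = rng.integers(0, 3, size=40)
        relabeled = np.array(["xyz"[int(l)] for l in labels])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, i1 = discretize(values, labels)
            _, i2 = discretize(values, relabeled)
        assert i1["ameva"] == pytest.approx(i2["ameva"], rel=1e-12)

    def test_candidates_only_at_composition_changes(self):
        values = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        labels = np.array([0, 0, 0, 1, 1, 1])
        np.testing.assert_array_equal(candidate_cuts(values, labels), [3.5])


# ---------------------------------------------------------------------------
# Optimized variant
# ---------------------------------------------------------------------------

class TestOptimizedVariant:
    @pytest.mark.parametrize("seed", range(10))
    def test_original_cuts_subset_of_optimized(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=60)
        labels = rng.integers(1, 6, size=60)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s_orig, _ = discretize(values, labels, variant="original")
            s_opt, _ = discretize(values, labels, variant="optimized")
        assert set(s_orig.cuts).issubset(set(s_opt.cuts))

    def test_optimized_generates_more_intervals_on_noisy_data(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=120)
        labels = rng.integers(1, 6, size=120)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s_orig, _ = discretize(values, labels, variant="original")
            s_opt, _ = discretize(values, labels, variant="optimized")
        assert s_opt.k >= s_orig.k

    @pytest.mark.parametrize("seed", range(5))
    def test_criterion_evaluation_count_proxy(self, seed):
        """The one-pass optimized search touches each candidate at most
        once, never more often than the iterative original search."""
        rng = np.random.default_rng(seed + 100)
        values = rng.normal(size=80)
        labels = rng.integers(1, 6, size=80)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, i_orig = discretize(values, labels, variant="original")
            _, i_opt = discretize(values, labels, variant="optimized")
        assert i_opt["n_criterion_evals"] <= i_orig["n_criterion_evals"]

    def test_scheme_serialization_round_trip(self, tmp_path, rng):
        from adlike import DiscretizationScheme

        values = rng.normal(size=50)
        labels = rng.integers(1, 4, size=50)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fs, _ = discretize(values, labels, variant="optimized")
        scheme = DiscretizationScheme(features={"f0": fs}, variant="optimized")
        path = tmp_path / "scheme.json"
        scheme.to_json(path)
        back = DiscretizationScheme.from_json(path)
        np.testing.assert_allclose(back.features["f0"].cuts, fs.cuts)
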