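"""Oracle suite and closed-form checks for the nine normalization methods.

Each scaling method is compared against a deliberately naive, loop-based
re-implementation written here (shared percentile convention: linear
interpolation).  The count-replacing methods are checked through their
defining properties (identical sorted columns; conserved depth).
"""

import math

import numpy as np
import pytest

from metanorm import CountMatrix, METHODS, normalize
from metanorm.normalization import (
    norm_css,
    norm_median,
    norm_quantile_quantile,
    norm_rarefy,
    norm_rcss,
    norm_rle,
    norm_tmm,
    norm_total_count,
    norm_upper_quartile,
    rescale_to_geometric_mean,
)
from .conftest import random_count_matrix


# ---------------------------------------------------------------------------
# naive oracles


def oracle_total(cm):
    return [sum(cm.counts[i, j] for i in range(cm.n_genes)) for j in range(cm.n_samples)]


def oracle_percentile(cm, pct):
    gstar = [i for i in range(cm.n_genes) if cm.counts[i].sum() > 0]
    return [
        np.percentile([cm.counts[i, j] for i in gstar], pct)
        for j in range(cm.n_samples)
    ]


def oracle_rle(cm):
    all_pos = [i for i in range(cm.n_genes) if all(cm.counts[i] > 0)]
    geo = {
        i: math.exp(sum(math.log(v) for v in cm.counts[i]) / cm.n_samples)
        for i in all_pos
    }
    return [
        np.median([cm.counts[i, j] / geo[i] for i in all_pos])
        for j in range(cm.n_samples)
    ]


def oracle_rcss(cm):
    out = []
    for j in range(cm.n_samples):
        col = cm.counts[:, j]
        med = np.percentile(col, 50)
        out.append(sum(v for v in col if v >= med))
    return out


def oracle_tmm_f(cm, j, r, trim_m=0.30, trim_a=0.05):
    """Explicit sort-trim-weight enumeration of the TMM adjustment."""
    tj = cm.counts[:, j].sum()
    tr = cm.counts[:, r].sum()
    rows = [
        i for i in range(cm.n_genes) if cm.counts[i, j] > 0 and cm.counts[i, r] > 0
    ]
    m_vals, a_vals, w_vals = [], [], []
    for i in rows:
        yj, yr = cm.counts[i, j], cm.counts[i, r]
        pj, pr = yj / tj, yr / tr
        m_vals.append(math.log2(pj / pr))
        a_vals.append(0.5 * math.log2(pj * pr))
        w_vals.append(1.0 / ((tj - yj) / (tj * yj) + (tr - yr) / (tr * yr)))
    n = len(rows)
    keep = set(range(n))
    for vals, trim in ((m_vals, trim_m), (a_vals, trim_a)):
        cut = int(np.floor(n * trim / 2))
        order = sorted(range(n), key=lambda k: (vals[k], k))
        keep -= set(order[:cut])
        keep -= set(order[n - cut:])
    num = sum(w_vals[k] * m_vals[k] for k in keep)
    den = sum(w_vals[k] for k in keep)
    return 2.0 ** (num / den)


def oracle_css(cm, stability_threshold=0.10):
    """Independent re-implementation of the documented CSS selection rule."""
    levels = [round(0.01 * k, 2) for k in range(101)]
    q = np.array(
        [
            [np.percentile(cm.counts[cm.counts[:, j] > 0, j], l * 100) for j in range(cm.n_samples)]
            for l in levels
        ]
    )
    ref = np.median(q, axis=1)
    d = np.median(np.abs(q - ref[:, None]), axis=1)
    l_hat = 0.50
    if np.any(d > 0):
        for i, l in enumerate(levels):
            if l < 0.50 or i == 0 or d[i] <= 0:
                continue
            if (d[i] - d[i - 1]) / d[i] > stability_threshold:
                l_hat = l
                break
        else:
            l_hat = 0.50
    idx = levels.index(round(l_hat, 2))
    out = []
    for j in range(cm.n_samples):
        thr = q[idx, j]
        out.append(sum(v for v in cm.counts[:, j] if v <= thr))
    return out, l_hat


# ---------------------------------------------------------------------------
# oracle equivalence on random matrices


@pytest.mark.parametrize("seed", range(12))
def test_scaling_factors_match_bruteforce(seed):
    rng = np.random.default_rng(seed)
    cm = random_count_matrix(rng, 50, 6, lam=10.0, zero_frac=0.25)
    assert np.allclose(norm_total_count(cm).factors, oracle_total(cm), atol=1e-10)
    assert np.allclose(norm_median(cm).factors, oracle_percentile(cm, 50), atol=1e-10)
    assert np.allclose(
        norm_upper_quartile(cm).factors, oracle_percentile(cm, 75), atol=1e-10
    )
    assert np.allclose(norm_rle(cm).factors, oracle_rle(cm), atol=1e-10)
    assert np.allclose(norm_rcss(cm).factors, oracle_rcss(cm), atol=1e-10)


@pytest.mark.parametrize("seed", range(6))
def test_tmm_matches_sort_trim_weight_enumeration(seed):
    rng = np.random.default_rng(100 + seed)
    cm = random_count_matrix(rng, 200, 6, lam=20.0, zero_frac=0.15)
    res = norm_tmm(cm, reference=cm.sample_ids[0])
    f = res.internals.tmm_adjustment
    assert f[0] == 1.0
    for j in range(1, cm.n_samples):
        assert f[j] == pytest.approx(oracle_tmm_f(cm, j, 0), abs=1e-10)


@pytest.mark.parametrize("seed", range(4))
def test_css_matches_independent_reimplementation(seed):
    rng = np.random.default_rng(200 + seed)
    cm = random_count_matrix(rng, 500, 10, lam=6.0, zero_frac=0.3)
    res = norm_css(cm)
    expected, l_hat = oracle_css(cm)
    assert res.internals.css_quantile == pytest.approx(l_hat)
    assert np.allclose(res.factors, expected, atol=1e-10)


# ---------------------------------------------------------------------------
# closed forms and hand examples


def _cm(arr, n_prefix="g", s_prefix="s"):
    arr = np.asarray(arr)
    return CountMatrix(
        arr,
        [f"{n_prefix}{i}" for i in range(arr.shape[0])],
        [f"{s_prefix}{j}" for j in range(arr.shape[1])],
    )


class TestClosedForms:
    def test_total_count_hand_example(self):
        assert norm_total_count(_cm([[1, 2], [3, 4]])).factors.tolist() == [4.0, 6.0]

    def test_total_count_zero_sample_raises(self):
        with pytest.raises(ValueError):
            norm_total_count(_cm([[1, 0], [2, 0]]))

    def test_median_excludes_allzero_genes(self):
        res = norm_median(_cm([[0, 0], [2, 4], [6, 8]]))
        assert res.factors.tolist() == [4.0, 6.0]

    def test_upper_quartile_linear_interpolation(self):
        res = norm_upper_quartile(_cm([[1], [2], [3], [4]]))
        assert res.factors[0] == pytest.approx(3.25)

    def test_tmm_identical_samples_f_is_one(self):
        col = np.array([5, 10, 20, 40, 80])
        res = norm_tmm(_cm(np.column_stack([col, col])))
        assert np.allclose(res.internals.tmm_adjustment, 1.0)
        assert np.allclose(res.factors, [155.0, 155.0])

    def test_tmm_proportional_samples_f_is_one(self):
        col = np.array([5, 10, 20, 40, 80])
        res = norm_tmm(_cm(np.column_stack([col, 2 * col])))
        assert np.allclose(res.internals.tmm_adjustment, 1.0)
        assert res.factors[1] / res.factors[0] == pytest.approx(2.0)

    def test_tmm_f_nearly_depth_invariant(self, rng):
        # M, A and the trimmed gene set depend only on relative abundances,
        # so scaling one sample leaves f almost unchanged; the residual
        # drift comes from the count-based inverse-variance weights.
        cm = random_count_matrix(rng, 150, 4, lam=15.0, zero_frac=0.1)
        scaled = _cm(
            np.column_stack(
                [cm.counts[:, 0] * 7] + [cm.counts[:, j] for j in range(1, 4)]
            )
        )
        f0 = norm_tmm(cm, reference=cm.sample_ids[-1]).internals.tmm_adjustment
        f1 = norm_tmm(scaled, reference=scaled.sample_ids[-1]).internals.tmm_adjustment
        assert np.allclose(f0[1:], f1[1:], atol=1e-12)
        assert f1[0] == pytest.approx(f0[0], rel=0.05)

    def test_rle_identical_samples_unit_factors(self):
        col = np.array([3, 6, 9])
        res = norm_rle(_cm(np.column_stack([col, col, col])))
        assert np.allclose(res.factors, 1.0)

    def test_rle_exact_multiple_recovers_scalar(self):
        col = np.array([4, 8, 16])
        res = norm_rle(_cm(np.column_stack([col, 3 * col])))
        assert res.factors[1] / res.factors[0] == pytest.approx(3.0)
        assert res.factors[0] == pytest.approx(3 ** -0.5)
        assert res.factors[1] == pytest.approx(3 ** 0.5)

    def test_rle_no_allpositive_gene_raises(self):
        with pytest.raises(ValueError, match="filter"):
            norm_rle(_cm([[0, 1], [1, 0]]))

    def test_rle_multi_column_scalars_recovered_up_to_constant(self, rng):
        base = rng.integers(1, 50, size=30)
        scalars = np.array([1.0, 2.0, 4.0])
        counts = np.column_stack([(base * c).astype(int) for c in [1, 2, 4]])
        res = norm_rle(_cm(counts))
        ratios = res.factors / res.factors[0]
        assert np.allclose(ratios, scalars, rtol=1e-12)

    def test_css_identical_samples_falls_back_to_median_level(self):
        col = np.array([1, 2, 3, 4, 100])
        res = norm_css(_cm(np.column_stack([col, col, col])))
        assert res.internals.css_quantile == pytest.approx(0.50)
        # median of positives is 3; sum of counts <= 3 is 6, equal across samples
        assert np.allclose(res.factors, 6.0)

    def test_rcss_hand_example_inclusive_median(self):
        res = norm_rcss(_cm([[1], [2], [3], [4], [5]]))
        assert res.factors[0] == pytest.approx(12.0)

    def test_rcss_exclusive_option(self):
        res = norm_rcss(_cm([[1], [2], [3], [4], [5]]), inclusive=False)
        assert res.factors[0] == pytest.approx(9.0)

    @pytest.mark.parametrize(
        "method", ["total_count", "median", "upper_quartile", "rcss"]
    )
    def test_positive_homogeneity(self, rng, method):
        cm = random_count_matrix(rng, 80, 4, lam=10.0, zero_frac=0.2)
        c = 3
        scaled = _cm(
            np.column_stack(
                [cm.counts[:, 0] * c] + [cm.counts[:, j] for j in range(1, 4)]
            )
        )
        base = normalize(cm, method).factors
        out = normalize(scaled, method).factors
        assert out[0] == pytest.approx(c * base[0], rel=1e-12)
        assert np.allclose(out[1:], base[1:])


class TestQuantileQuantile:
    def test_reference_from_three_known_columns(self):
        # sorted columns [0,1,4], [0,2,6], [0,3,8] -> per-rank medians [0,2,6]
        counts = np.column_stack([[0, 1, 4], [0, 2, 6], [0, 3, 8]])
        res = norm_quantile_quantile(_cm(counts), np.random.default_rng(0))
        assert sorted(res.internals.qq_reference.tolist()) == [0, 2, 6]
        for j in range(3):
            assert sorted(res.transformed.counts[:, j].tolist()) == [0, 2, 6]

    def test_rank_matching_preserves_order_without_ties(self):
        counts = np.column_stack([[10, 1, 4], [6, 0, 2], [8, 0, 3]])
        res = norm_quantile_quantile(_cm(counts), np.random.default_rng(0))
        ref = sorted(res.internals.qq_reference.tolist())
        col0 = res.transformed.counts[:, 0]
        # gene order by raw count in column 0 is g1 < g2 < g0
        assert col0[1] == ref[0] and col0[2] == ref[1] and col0[0] == ref[2]

    def test_sorted_columns_identical_after_transform(self, rng):
        cm = random_count_matrix(rng, 60, 5, zero_frac=0.3)
        res = norm_quantile_quantile(cm, np.random.default_rng(1))
        cols = np.sort(res.transformed.counts, axis=0)
        for j in range(1, 5):
            assert np.array_equal(cols[:, 0], cols[:, j])

    def test_fixed_point_up_to_tie_permutation_odd_n(self):
        col = np.array([0, 1, 4, 9])
        counts = np.column_stack([col, col[::-1], col])
        res = norm_quantile_quantile(_cm(counts), np.random.default_rng(2))
        for j in range(3):
            assert sorted(res.transformed.counts[:, j].tolist()) == [0, 1, 4, 9]

    def test_factors_all_one(self, rng):
        cm = random_count_matrix(rng, 20, 4)
        res = norm_quantile_quantile(cm, np.random.default_rng(0))
        assert np.all(res.factors == 1.0)


class TestRarefy:
    def test_depth_equal_to_total_is_identity(self):
        cm = _cm([[5, 9], [3, 1]])
        res = norm_rarefy(cm, np.random.default_rng(0), depth=8)
        assert np.array_equal(res.transformed.counts[:, 0], [5, 3])

    def test_single_support_column(self):
        cm = _cm([[5, 5], [0, 5]])
        res = norm_rarefy(cm, np.random.default_rng(0), depth=3)
        assert res.transformed.counts[0, 0] == 3
        assert res.transformed.counts[1, 0] == 0

    def test_column_sums_all_equal_depth(self, rng):
        cm = random_count_matrix(rng, 40, 6, lam=20.0)
        res = norm_rarefy(cm, np.random.default_rng(3))
        depth = res.internals.rarefy_depth
        assert depth == cm.counts.sum(axis=0).min()
        assert np.all(res.transformed.counts.sum(axis=0) == depth)
        assert np.all(res.transformed.counts <= cm.counts)

    def test_depth_exceeding_total_raises(self):
        cm = _cm([[5, 9], [3, 1]])
        with pytest.raises(ValueError):
            norm_rarefy(cm, np.random.default_rng(0), depth=9)

    def test_hypergeometric_mean(self):
        cm = _cm([[50], [50]])
        g = np.random.default_rng(5)
        draws = [
            norm_rarefy(cm, g, depth=10).transformed.counts[0, 0]
            for _ in range(10_000)
        ]
        # mean 5, variance n*K/N*(1-K/N)*(N-n)/(N-1) = 10*.25*90/99
        se = np.sqrt(10 * 0.25 * 90 / 99 / 10_000)
        assert abs(np.mean(draws) - 5.0) < 3 * se


class TestDispatcher:
    def test_unknown_method_lists_choices(self, small_cm):
        with pytest.raises(ValueError, match="total_count"):
            normalize(small_cm, "clr")

    def test_tmm_result_carries_internals(self, small_cm):
        res = normalize(small_cm, "tmm")
        assert res.method == "tmm"
        assert res.internals.tmm_adjustment is not None
        assert res.internals.tmm_reference in small_cm.sample_ids

    def test_rarefy_result_shape(self, small_cm):
        res = normalize(small_cm, "rarefy", rng=np.random.default_rng(0))
        assert np.all(res.factors == 1.0)
        assert res.transformed is not None

    def test_stochastic_methods_require_rng(self, small_cm):
        with pytest.raises(ValueError, match="random"):
            normalize(small_cm, "quantile_quantile")

    def test_factors_track_depth_on_synthetic_data(self, synthetic_cm):
        from scipy.stats import spearmanr

        totals = synthetic_cm.counts.sum(axis=0)
        for method in ("total_count", "median", "upper_quartile", "tmm", "rle", "css", "rcss"):
            factors = rescale_to_geometric_mean(normalize(synthetic_cm, method).factors)
            rho = spearmanr(factors, totals).statistic
            assert rho > 0.5, method


def test_method_registry_is_the_nine_study_methods():
    assert set(METHODS) == {
        "total_count",
        "median",
        "upper_quartile",
        "tmm",
        "rle",
        "css",
        "rcss",
        "quantile_quantile",
        "rarefy",
    }
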