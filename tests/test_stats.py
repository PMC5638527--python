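import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst
from scipy.stats import rankdata, studentized_range

from ppct.stats import (
    CollinearityError,
    compare_correlations,
    mann_whitney,
    regress_standardized,
    spearman,
    steel_dwass,
    studentized_range_sf,
)

# ---------------------------------------------------------------------------
# independent oracles


def brute_spearman_r(x, y):
    """Rank by hand (argsort + tie averaging), then textbook Pearson."""
    def midranks(v):
        v = np.asarray(v, float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sv[j + 1] == sv[i]:
                j += 1
            ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    mx, my = rx.mean(), ry.mean()
    num = np.sum((rx - mx) * (ry - my))
    den = math.sqrt(np.sum((rx - mx) ** 2) * np.sum((ry - my) ** 2))
    return num / den


def brute_exact_mw_p(a, b):
    """Enumerate group assignments, computing U by pairwise comparison."""
    pooled = list(a) + list(b)
    m = len(a)

    def u_stat(group_a, group_b):
        return sum(
            1.0 if x > y else (0.5 if x == y else 0.0)
            for x in group_a for y in group_b
        )

    center = m * len(b) / 2.0
    observed = abs(u_stat(a, b) - center)
    hits = total = 0
    for idx in itertools.combinations(range(len(pooled)), m):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_stat(ga, gb) - center) >= observed - 1e-12:
            hits += 1
    return hits / total


def permutation_steel_dwass(groups, n_shuffles, seed):
    """Max-|z| permutation reference for the all-pairs adjusted p-values."""
    sizes = [len(g) for g in groups]
    pooled = np.concatenate(groups)
    edges = np.cumsum([0] + sizes)
    pairs = list(itertools.combinations(range(len(groups)), 2))

    def pair_z(a, b):
        m, n = len(a), len(b)
        r = rankdata(np.concatenate([a, b]))
        w = r[:m].sum()
        e = m * (m + n + 1) / 2.0
        c = r - r.mean()
        var = m * n / ((m + n) * (m + n - 1.0)) * np.dot(c, c)
        return 0.0 if var == 0 else (w - e) / math.sqrt(var)

    def split(v):
        return [v[edges[i]:edges[i + 1]] for i in range(len(sizes))]

    obs = {p: abs(pair_z(groups[p[0]], groups[p[1]])) for p in pairs}
    rng = np.random.default_rng(seed)
    max_abs = np.empty(n_shuffles)
    for k in range(n_shuffles):
        parts = split(rng.permutation(pooled))
        max_abs[k] = max(abs(pair_z(parts[i], parts[j])) for i, j in pairs)
    return {p: float(np.mean(max_abs >= obs[p])) for p in pairs}


# ---------------------------------------------------------------------------


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3], [10, 20, 30]).r == pytest.approx(1.0)
        assert spearman([1, 2, 3], [30, 20, 10]).r == pytest.approx(-1.0)

    def test_tied_example_matches_brute_force(self):
        x, y = [1, 2, 2, 4], [3, 1, 4, 4]
        assert spearman(x, y).r == pytest.approx(brute_spearman_r(x, y))

    def test_random_tied_vectors_match_brute_force(self, rng):
        for _ in range(50):
            n = rng.integers(4, 12)
            x = rng.integers(0, 5, n).astype(float)
            y = rng.integers(0, 5, n).astype(float)
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            assert spearman(x, y).r == pytest.approx(brute_spearman_r(x, y), abs=1e-12)

    def test_zero_rank_variance_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [1, 2])

    @settings(max_examples=60, derandomize=True)
    @given(hst.lists(hst.integers(min_value=-100, max_value=100),
                     min_size=4, max_size=20, unique=True))
    def test_invariant_under_monotone_transform(self, xs):
        rng = np.random.default_rng(0)
        y = rng.normal(size=len(xs))
        x = np.asarray(xs, dtype=float)
        base = spearman(x, y)
        warped = spearman(x ** 3 + 2.0 * x, y)  # strictly increasing, float-exact on ints
        assert warped.r == pytest.approx(base.r, abs=1e-12)


class TestRegressStandardized:
    def test_single_predictor_beta_is_pearson_r(self, rng):
        x = rng.normal(size=60)
        y = 0.4 * x + rng.normal(size=60)
        res = regress_standardized(y, x[:, None], ["x"])
        r = np.corrcoef(x, y)[0, 1]
        assert res.coefficients["x"] == pytest.approx(r, abs=1e-12)

    def test_orthogonal_predictors_give_marginal_correlations(self, rng):
        raw = rng.normal(size=(80, 2))
        q, _ = np.linalg.qr(raw - raw.mean(axis=0))
        X = q * math.sqrt(79)  # exactly orthogonal, unit sample variance
        y = 0.5 * X[:, 0] - 0.3 * X[:, 1] + rng.normal(size=80)
        res = regress_standardized(y, X, ["a", "b"])
        # normal equations computed independently on z-scores
        yz = (y - y.mean()) / y.std(ddof=1)
        for j, nm in enumerate(("a", "b")):
            marginal = float(np.corrcoef(X[:, j], y)[0, 1])
            assert res.coefficients[nm] == pytest.approx(marginal, abs=1e-10)
            assert res.coefficients[nm] == pytest.approx(float(X[:, j] @ yz) / 79.0, abs=1e-10)

    def test_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        X = rng.normal(size=(50, 3))
        y = X @ [0.5, -0.2, 0.1] + rng.normal(size=50)
        res = regress_standardized(y, X, ["a", "b", "c"])
        Xz = (X - X.mean(0)) / X.std(0, ddof=1)
        yz = (y - y.mean()) / y.std(ddof=1)
        fit = sm.OLS(yz, sm.add_constant(Xz)).fit()
        assert np.allclose(list(res.coefficients.values()), fit.params[1:], atol=1e-10)
        assert np.allclose(list(res.p_values.values()), fit.pvalues[1:], atol=1e-10)

    def test_invariant_to_affine_rescaling(self, rng):
        X = rng.normal(size=(40, 3))
        y = X @ [1.0, 0.5, -0.5] + rng.normal(size=40)
        a = regress_standardized(y, X, ["a", "b", "c"])
        X2 = X * np.array([3.0, 0.1, 100.0]) + np.array([5.0, -2.0, 0.0])
        b = regress_standardized(y * 10.0 - 4.0, X2, ["a", "b", "c"])
        for nm in ("a", "b", "c"):
            assert a.coefficients[nm] == pytest.approx(b.coefficients[nm], abs=1e-10)

    def test_duplicated_predictor_rejected(self, rng):
        x = rng.normal(size=30)
        with pytest.raises(CollinearityError):
            regress_standardized(rng.normal(size=30), np.column_stack([x, x]), ["a", "b"])


class TestMannWhitney:
    def test_identical_samples(self):
        a = np.arange(10.0)
        assert mann_whitney(a, a) == pytest.approx(1.0)

    def test_extreme_separation(self):
        p = mann_whitney([1.0, 2.0, 3.0], [100.0, 101.0, 102.0])
        assert p < 0.1  # minimal attainable for 3+3 under the normal approximation

    def test_exact_matches_enumeration_with_ties(self, rng):
        for _ in range(25):
            a = rng.integers(0, 4, 4).astype(float)
            b = rng.integers(0, 4, 4).astype(float)
            assert mann_whitney(a, b, method="exact") == pytest.approx(
                brute_exact_mw_p(a, b), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestStudentizedRange:
    @pytest.mark.parametrize("k", [2, 3, 8])
    def test_matches_scipy_tail(self, k):
        q = np.array([0.5, 1.5, 2.772, 3.5, 5.0])
        ours = studentized_range_sf(q, k)
        ref = studentized_range.sf(q, k, 1e7)
        assert np.allclose(ours, ref, atol=1e-6)

    def test_k2_reduces_to_normal_two_sided(self):
        from scipy.stats import norm
        z = 1.7
        assert studentized_range_sf(math.sqrt(2) * z, 2) == pytest.approx(
            2 * norm.sf(z), abs=1e-8)


class TestSteelDwass:
    def test_identical_groups_not_significant(self):
        g = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = steel_dwass([g, list(g), list(g)])
        assert all(p > 0.999 for p in res.p_values.values())

    def test_separated_third_group(self):
        g1 = list(range(1, 11))
        g2 = list(range(1, 11))
        g3 = list(range(101, 111))
        res = steel_dwass([g1, g2, g3])
        assert res.p_value(0, 1) > 0.99
        assert res.p_value(0, 2) < 0.01
        assert res.p_value(1, 2) < 0.01

    def test_k2_equals_mann_whitney(self, rng):
        for _ in range(10):
            a = rng.normal(size=12)
            b = rng.normal(0.5, 1.0, size=9)
            res = steel_dwass([a, b])
            assert res.p_value(0, 1) == pytest.approx(mann_whitney(a, b), abs=1e-9)

    def test_adjustment_penalizes_for_k3(self, rng):
        groups = [rng.normal(size=10) for _ in range(3)]
        res = steel_dwass(groups)
        for (i, j), p_adj in res.p_values.items():
            unadjusted = mann_whitney(groups[i], groups[j])
            assert p_adj >= unadjusted - 1e-12

    def test_matches_permutation_reference(self, rng):
        groups = [rng.normal(0.0, 1.0, 15), rng.normal(0.6, 1.0, 15), rng.normal(1.2, 1.0, 15)]
        res = steel_dwass(groups)
        ref = permutation_steel_dwass(groups, n_shuffles=4000, seed=77)
        for pair, p_ref in ref.items():
            mc_se = math.sqrt(max(p_ref * (1 - p_ref), 1e-4) / 4000)
            assert res.p_values[pair] == pytest.approx(p_ref, abs=max(0.04, 4 * mc_se))

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            steel_dwass([[1.0], [1.0, 2.0]])


class TestCompareCorrelations:
    def test_equal_correlations(self):
        assert compare_correlations(0.3, 50, 0.3, 60) == pytest.approx(1.0)

    def test_hand_computed_case(self):
        # z = atanh(0.8) / sqrt(2/47) = 1.0986/0.2063 = 5.33
        p = compare_correlations(0.8, 50, 0.0, 50)
        z = math.atanh(0.8) / math.sqrt(2.0 / 47.0)
        assert z == pytest.approx(5.33, abs=0.01)
        assert p < 1e-6

    def test_symmetric_in_arguments(self):
        assert compare_correlations(0.5, 30, 0.1, 80) == pytest.approx(
            compare_correlations(0.1, 80, 0.5, 30))

    def test_degenerate_correlation_rejected(self):
        with pytest.raises(ValueError):
            compare_correlations(1.0, 30, 0.0, 30)
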