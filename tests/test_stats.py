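"""Permutation tests, FDR, correlations, nested-CV regression."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from avafp.stats import (
    fdr_bh,
    nested_cv_regression,
    nrmse,
    pearson_test,
    perm_posthoc,
    permanova_oneway,
    spearman,
)


def bh_oracle(p):
    """Textbook step-up BH adjustment."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        val = min(prev, p[idx] * m / rank)
        adj[idx] = val
        prev = val
    return np.minimum(adj, 1.0)


class TestPermanova:
    def test_f_matches_classical_anova(self, rng):
        vals = rng.standard_normal(30)
        labels = np.repeat(["a", "b", "c"], 10)
        res = permanova_oneway(vals, labels, n_perm=99, seed=0)
        f_ref = sps.f_oneway(vals[:10], vals[10:20], vals[20:]).statistic
        assert res.statistic == pytest.approx(f_ref, abs=1e-10)

    def test_huge_shift_gives_minimal_p(self, rng):
        vals = np.concatenate([rng.standard_normal(20), 10 + rng.standard_normal(20)])
        labels = np.repeat(["a", "b"], 20)
        res = permanova_oneway(vals, labels, n_perm=999, seed=1)
        assert res.p_perm == pytest.approx(1 / 1000)

    def test_deterministic_given_seed(self, rng):
        vals = rng.standard_normal(24)
        labels = np.repeat(["a", "b", "c"], 8)
        a = permanova_oneway(vals, labels, n_perm=500, seed=7)
        b = permanova_oneway(vals, labels, n_perm=500, seed=7)
        assert a.p_perm == b.p_perm and a.statistic == b.statistic

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="'b'"):
            permanova_oneway([1.0, 2.0, 3.0], ["a", "a", "b"], n_perm=10, seed=0)


class TestPermPosthoc:
    def test_identical_samples(self):
        res = perm_posthoc([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], n_perm=99, seed=0)
        assert res.statistic == 0 and res.p_perm == 1.0

    def test_separated_samples_near_minimal_p(self):
        # only shuffles reproducing the pure split tie the observed statistic,
        # so p sits at the bottom of the attainable range (up to tie sampling)
        res = perm_posthoc([0.0] * 5, [10.0] * 5, n_perm=999, seed=0)
        assert 1 / 1000 <= res.p_perm <= 0.03

    def test_p_lower_bound(self, rng):
        a, b = rng.standard_normal(6), rng.standard_normal(6)
        res = perm_posthoc(a, b, n_perm=200, seed=0)
        assert res.p_perm >= 1 / 201


class TestFdrBh:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.2], [0.2]),
            ([0.01, 0.5], [0.02, 0.5]),
        ],
    )
    def test_hand_examples(self, p, expected):
        np.testing.assert_allclose(fdr_bh(p), expected, atol=1e-12)

    def test_matches_oracle_on_random_vectors(self, rng):
        for _ in range(300):
            p = rng.random(int(rng.integers(1, 25)))
            np.testing.assert_allclose(fdr_bh(p), bh_oracle(p), atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.2])


class TestCorrelations:
    def test_perfect_linear(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, p = pearson_test(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-6

    def test_negative_monotone(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert spearman(x, -x) == pytest.approx(-1.0)

    def test_hand_rank_correlation(self):
        assert spearman([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestNrmse:
    def test_perfect(self):
        assert nrmse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_hand_example(self):
        assert nrmse([1.0, 9.0], [0.0, 10.0]) == pytest.approx(0.1)

    def test_constant_bias_closed_form(self):
        y = np.array([0.0, 2.0, 4.0])
        assert nrmse(y + 1.0, y) == pytest.approx(1.0 / 4.0)

    def test_zero_range_rejected(self):
        with pytest.raises(ValueError):
            nrmse([1.0, 2.0], [3.0, 3.0])


class TestNestedCvRegression:
    def _design(self, rng, n=34):
        return pd.DataFrame(
            {
                "hemisphere": (rng.random(n) < 0.5).astype(float),
                "gender": (rng.random(n) < 0.5).astype(float),
                "age": rng.normal(40, 15, n),
                "iclinical": rng.normal(0.5, 0.15, n),
            }
        )

    def test_noiseless_linear_is_perfect(self, rng):
        X = self._design(rng)
        z = (X - X.mean()) / X.std(ddof=1)
        y = (1.5 + 0.3 * z["age"] - 0.2 * z["iclinical"] + 0.1 * z["gender"]).to_numpy()
        rep = nested_cv_regression(X, y, k=5, n_iter=20, seed=0)
        assert rep.nrmse == pytest.approx(0.0, abs=1e-10)
        assert rep.r2 == pytest.approx(1.0, abs=1e-10)
        assert rep.spearman == pytest.approx(1.0, abs=1e-10)
        assert rep.beta["age"] == pytest.approx(0.3, abs=1e-10)

    def test_rank_deficient_design_reported(self, rng):
        X = self._design(rng)
        X["dup"] = X["age"] * 2.0
        with pytest.raises(ValueError, match="dup|age"):
            nested_cv_regression(X, rng.standard_normal(34), seed=0)

    def test_deterministic_given_seed(self, rng):
        X = self._design(rng)
        y = rng.standard_normal(34)
        a = nested_cv_regression(X, y, n_iter=5, seed=3)
        b = nested_cv_regression(X, y, n_iter=5, seed=3)
        assert a.nrmse == b.nrmse and a.r2 == b.r2 and a.spearman == b.spearman

    def test_more_iterations_stabilize_metrics(self):
        # SD of the CV metric across reruns shrinks with iteration count
        rng = np.random.default_rng(0)
        X = self._design(rng)
        y = (0.5 * X["age"] / 15 + rng.standard_normal(34)).to_numpy()
        lo = [
            nested_cv_regression(X, y, n_iter=3, seed=s).r2 for s in range(8)
        ]
        hi = [
            nested_cv_regression(X, y, n_iter=60, seed=s).r2 for s in range(8)
        ]
        assert np.std(hi) < np.std(lo)

    def test_r2_definitions_agree_on_noiseless_data(self, rng):
        X = self._design(rng)
        y = (X["age"] * 0.1 + X["iclinical"]).to_numpy()
        for definition in ("ss", "corr"):
            rep = nested_cv_regression(
                X, y, n_iter=5, seed=0, r2_definition=definition
            )
            assert rep.r2 == pytest.approx(1.0, abs=1e-9)


class TestPermutationCalibrationSmall:
    def test_null_p_distribution_is_uniformish(self, rng):
        # KS check on the attainable grid under an exchangeable null
        ps = []
        for i in range(300):
            r = np.random.default_rng(i)
            res = perm_posthoc(
                r.standard_normal(8), r.standard_normal(8), n_perm=99, seed=i
            )
            ps.append(res.p_perm)
        stat = sps.kstest(ps, "uniform").statistic
        assert stat < 0.1
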