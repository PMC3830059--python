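"""GFP, cluster randomization tests, TCT and Holm correction.

The enumeration oracles here re-derive the full cluster-test pipeline with
plain loops over explicitly enumerated permutations, independently of the
vectorised implementation, and require *exact* agreement of the
Monte-Carlo p with the implementation's exhaustive mode.
"""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from p3attn.gfp_stats import (
    StatError,
    cluster_test_conditions,
    cluster_test_vs_baseline,
    gfp,
    gfp_timecourse,
    holm_correct,
    tct,
)

# ---------------------------------------------------------------------------
# GFP


class TestGfp:
    def test_two_channel_antisymmetric_closed_form(self):
        a = 3.25
        erp = np.array([[a, -a, 0.5 * a], [-a, a, -0.5 * a]])
        np.testing.assert_allclose(gfp(erp), [a, a, 0.5 * a])

    def test_uniform_map_is_zero(self):
        assert gfp(np.full((7, 4), 2.2)).max() < 1e-12

    def test_matches_brute_force_formula(self, rng):
        erp = rng.standard_normal((91, 10))
        expected = np.empty(10)
        for t in range(10):
            v = erp[:, t]
            expected[t] = np.sqrt(np.sum((v - v.mean()) ** 2) / len(v))
        np.testing.assert_allclose(gfp(erp), expected, rtol=1e-12)

    def test_single_channel_rejected(self):
        with pytest.raises(StatError):
            gfp(np.ones((1, 5)))

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1), st.floats(-50, 50))
    def test_invariances(self, seed, offset):
        """GFP is invariant to channel permutation and to adding a
        spatially constant offset."""
        r = np.random.default_rng(seed)
        erp = r.standard_normal((12, 6))
        base = gfp(erp)
        np.testing.assert_allclose(gfp(erp[r.permutation(12)]), base,
                                   rtol=1e-10)
        np.testing.assert_allclose(gfp(erp + offset), base, atol=1e-8)

    def test_timecourse_container(self, rng, times):
        items = rng.standard_normal((5, 8, len(times)))
        tc = gfp_timecourse(items, times)
        assert tc.n_inputs == 5 and (tc.values >= 0).all()


# ---------------------------------------------------------------------------
# enumeration oracles (independent plain-loop reimplementation)


def _oracle_stat(D, direction):
    if direction == "two-sided":
        return np.abs(D)
    return D if direction == "greater" else -D


def _oracle_gfp(avg):
    out = np.empty(avg.shape[1])
    for t in range(avg.shape[1]):
        v = avg[:, t]
        out[t] = np.sqrt(np.mean((v - v.mean()) ** 2))
    return out


def _oracle_largest_cluster(sig, z):
    best, cur, found = 0.0, 0.0, False
    best_set = False
    i = 0
    while i < len(sig):
        if sig[i]:
            j = i
            s = 0.0
            while j < len(sig) and sig[j]:
                s += z[j]
                j += 1
            if not best_set or s > best:
                best, best_set = s, True
            i = j
        else:
            i += 1
    return best, best_set


def _oracle_cluster_p(S, alpha):
    """Shared tail: pointwise p/z from window maxima, clustering, then the
    leave-one-out null of largest cluster scores.  Row 0 is the observed
    labelling."""
    K, ns = S.shape
    M = S.max(axis=1)
    S_obs = S[0]
    p_pt = np.array([(1 + np.sum(M >= S_obs[t])) / (K + 1)
                     for t in range(ns)])
    z_pt = (S_obs - S.mean(axis=0)) / S.std(axis=0, ddof=1)
    sig = p_pt < alpha
    T_obs, found = _oracle_largest_cluster(sig, z_pt)
    if not found:
        return 1.0
    scores = np.zeros(K)
    tot, tot2 = S.sum(axis=0), (S**2).sum(axis=0)
    for k in range(K):
        p_k = np.array([np.sum(M >= S[k, t]) / K for t in range(ns)])
        m_loo = (tot - S[k]) / (K - 1)
        v_loo = (tot2 - S[k] ** 2 - (K - 1) * m_loo**2) / (K - 2)
        sd = np.sqrt(np.maximum(v_loo, 0.0))
        z_k = np.where(sd > 0, (S[k] - m_loo) / sd, 0.0)
        sc, fnd = _oracle_largest_cluster(p_k < alpha, z_k)
        scores[k] = sc if fnd else 0.0
    return (1 + np.sum(scores >= T_obs)) / (K + 1)


def oracle_conditions_p(A, B, times, window, alpha=0.05,
                        direction="two-sided"):
    mask = (times >= window[0]) & (times < window[1])
    Aw, Bw = A[:, :, mask], B[:, :, mask]
    X = np.concatenate([Aw, Bw], axis=0)
    n, nA = len(X), len(Aw)
    S = []
    for combo in itertools.combinations(range(n), nA):
        ia = list(combo)
        ib = [i for i in range(n) if i not in combo]
        D = _oracle_gfp(X[ia].mean(0)) - _oracle_gfp(X[ib].mean(0))
        S.append(_oracle_stat(D, direction))
    return _oracle_cluster_p(np.array(S), alpha)


def oracle_baseline_p(X, times, window, baseline, alpha=0.05):
    amask = (times >= window[0]) & (times < window[1])
    bmask = (times >= baseline[0]) & (times < baseline[1])
    A, B = X[:, :, amask], X[:, :, bmask]
    n = len(X)
    S = []
    for k in range(2**n):
        swap = [(k >> e) & 1 for e in range(n)]
        a = np.array([B[e] if s else A[e] for e, s in enumerate(swap)])
        b = np.array([A[e] if s else B[e] for e, s in enumerate(swap)])
        S.append(_oracle_gfp(a.mean(0)) - _oracle_gfp(b.mean(0)))
    return _oracle_cluster_p(np.array(S), alpha)


class TestEnumerationEquivalence:
    @pytest.mark.parametrize("direction", ["two-sided", "greater"])
    def test_conditions_exhaustive_matches_oracle(self, rng, direction):
        times = np.arange(10) * 4.0
        A = rng.standard_normal((4, 3, 10))
        A[:, 0, 3:7] += 1.5  # weak effect so clusters sometimes form
        B = rng.standard_normal((4, 3, 10))
        res = cluster_test_conditions(A, B, times, (0.0, 40.0),
                                      direction=direction, exhaustive=True)
        assert res.n_iter == 70  # C(8, 4)
        expected = oracle_conditions_p(A, B, times, (0.0, 40.0),
                                       direction=direction)
        assert res.p == expected

    def test_baseline_exhaustive_matches_oracle(self, rng):
        times = np.arange(16) * 4.0
        X = rng.standard_normal((6, 4, 16))
        X[:, 1, 8:12] += 1.0
        res = cluster_test_vs_baseline(X, times, (32.0, 64.0), (0.0, 32.0),
                                       exhaustive=True)
        assert res.n_iter == 64  # 2^6
        expected = oracle_baseline_p(X, times, (32.0, 64.0), (0.0, 32.0))
        assert res.p == expected

    def test_null_data_exhaustive_matches_oracle(self, rng):
        times = np.arange(12) * 4.0
        A = rng.standard_normal((4, 3, 12))
        B = rng.standard_normal((4, 3, 12))
        res = cluster_test_conditions(A, B, times, (0.0, 48.0),
                                      exhaustive=True)
        expected = oracle_conditions_p(A, B, times, (0.0, 48.0))
        assert res.p == expected


# ---------------------------------------------------------------------------
# behaviour of the Monte-Carlo tests


class TestClusterTests:
    def test_identical_sets_rarely_significant(self):
        """Randomly splitting one homogeneous set yields no significant
        cluster in nearly all seeds (exchangeable null)."""
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            X = r.standard_normal((30, 6, 20))
            times = np.arange(20) * 4.0
            res = cluster_test_conditions(X[:15], X[15:], times, (0.0, 80.0),
                                          n_iter=200, rng=seed)
            hits += res.significant
        # alpha-level test: 99.5-percentile band of Binomial(40, 0.05)
        assert hits <= 6

    def test_strong_effect_detected_with_correct_extent(self, rng):
        times = np.arange(50) * 4.0
        A = rng.standard_normal((40, 8, 50))
        B = rng.standard_normal((40, 8, 50))
        A[:, 0, 20:30] += 4.0  # channel-0 bump -> GFP difference
        res = cluster_test_conditions(A, B, times, (0.0, 200.0),
                                      n_iter=300, rng=1,
                                      direction="greater")
        assert res.significant and res.p <= 0.01
        lo, hi = res.extent_ms
        assert lo >= 60.0 and hi <= 130.0
        assert res.cluster_level_t > 0
        assert res.cluster_mean_t == pytest.approx(
            res.cluster_level_t
            / ((hi - lo) / 4.0 + 1), rel=1e-9)

    def test_baseline_test_detects_injected_response(self, rng):
        times = np.arange(40) * 4.0 - 80.0
        X = rng.standard_normal((40, 8, 40))
        X[:, 2, 25:35] += 2.0
        res = cluster_test_vs_baseline(X, times, (20.0, 80.0), (-80.0, -20.0),
                                       n_iter=300, rng=2)
        assert res.significant

    def test_unequal_windows_rejected_with_swap_message(self, rng, times):
        X = rng.standard_normal((5, 4, len(times)))
        with pytest.raises(StatError, match="swap"):
            cluster_test_vs_baseline(X, times, (100.0, 400.0), (-300.0, -100.0))

    def test_window_too_short(self, rng, times):
        X = rng.standard_normal((5, 4, len(times)))
        with pytest.raises(StatError, match="3 samples"):
            cluster_test_conditions(X[:2], X[2:], times, (0.0, 8.0))

    def test_low_iteration_warning(self, rng):
        times = np.arange(10) * 4.0
        X = rng.standard_normal((8, 4, 10))
        with pytest.warns(UserWarning, match="n_iter"):
            cluster_test_conditions(X[:4], X[4:], times, (0.0, 40.0),
                                    n_iter=50, rng=0)

    def test_p_never_zero_and_in_range(self, rng):
        times = np.arange(20) * 4.0
        A = rng.standard_normal((10, 5, 20)) + 5.0 * np.eye(5, 20)
        B = rng.standard_normal((10, 5, 20))
        res = cluster_test_conditions(A, B, times, (0.0, 80.0), n_iter=200,
                                      rng=3, direction="greater")
        assert 1.0 / 201 <= res.p <= 1.0

    def test_result_json_serialises(self, rng):
        times = np.arange(16) * 4.0
        X = rng.standard_normal((8, 4, 16))
        res = cluster_test_conditions(X[:4], X[4:], times, (0.0, 64.0),
                                      n_iter=100, rng=0)
        import json

        d = json.loads(res.to_json())
        assert {"p", "cluster_level_t", "window_ms",
                "significant"} <= set(d)


class TestTct:
    def test_consistent_topography_highly_significant(self, rng):
        topo = rng.standard_normal(12)
        X = topo[None, :, None] + 0.01 * rng.standard_normal((20, 12, 10))
        times = np.arange(10) * 4.0
        res = tct(X, times, (0.0, 40.0), n_iter=500, rng=0)
        assert res.window_p <= 0.01
        assert (res.pointwise_p > 0).all()

    def test_calibrated_under_channel_exchangeable_null(self):
        """With independently pre-shuffled channels the TCT window p is
        uniform: rejections at alpha=0.05 stay in the binomial band."""
        hits = 0
        n_sims = 100
        for seed in range(n_sims):
            r = np.random.default_rng(1_000 + seed)
            X = r.standard_normal((20, 12, 10))
            res = tct(X, np.arange(10) * 4.0, (0.0, 40.0), n_iter=200,
                      rng=seed)
            hits += res.window_p < 0.05
        # 95% band around 5 of 100
        assert 0 <= hits <= 10

    def test_single_consistent_epoch_less_significant_than_all(self, rng):
        topo = 3.0 * rng.standard_normal(12)
        times = np.arange(10) * 4.0
        all_consistent = (topo[None, :, None]
                          + 0.5 * rng.standard_normal((50, 12, 10)))
        one_strong = rng.standard_normal((50, 12, 10))
        one_strong[0] += 10 * topo[:, None]
        p_all = tct(all_consistent, times, (0.0, 40.0), n_iter=300,
                    rng=1).window_p
        p_one = tct(one_strong, times, (0.0, 40.0), n_iter=300,
                    rng=1).window_p
        assert p_all < p_one

    def test_input_validation(self, rng):
        times = np.arange(10) * 4.0
        with pytest.raises(StatError, match="2 epochs"):
            tct(rng.standard_normal((1, 5, 10)), times, (0.0, 40.0))
        with pytest.raises(StatError, match="3 channels"):
            tct(rng.standard_normal((5, 2, 10)), times, (0.0, 40.0))


class TestHolm:
    def test_hand_checked_step_down(self):
        reject, adj = holm_correct([0.001, 0.02, 0.04], alpha=0.05)
        assert reject.all()  # 0.001<0.05/3, 0.02<0.05/2, 0.04<0.05

    def test_single_and_degenerate_families(self):
        reject, _ = holm_correct([0.01])
        assert reject[0]
        reject, _ = holm_correct([1.0, 1.0, 1.0])
        assert not reject.any()

    def test_adjusted_monotone_after_sorting(self, rng):
        p = rng.random(12)
        _, adj = holm_correct(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(StatError):
            holm_correct([0.2, 1.4])
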