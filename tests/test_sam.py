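from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ohcpipe.sam import (
    SamDE,
    bh_fdr,
    estimate_s0,
    permutation_pvalues,
    pooled_se,
    sam_statistic,
)

LABELS_3V3 = ["A"] * 3 + ["B"] * 3


class TestSamStatistic:
    def test_zero_numerator_gives_zero(self):
        vals = np.array([[5.0, 5.0, 5.0, 5.0]])
        assert sam_statistic(vals, ["A", "A", "B", "B"], s0=0.7)[0] == 0.0

    def test_zero_variance_forced_by_formula(self):
        vals = np.array([[4.0, 4.0, 2.0, 2.0]])
        d = sam_statistic(vals, ["A", "A", "B", "B"], s0=0.5)
        assert pooled_se(vals, ["A", "A", "B", "B"])[0] == 0.0
        assert d[0] == pytest.approx(2.0 / 0.5)

    def test_large_s0_shrinks_d_to_zero(self, rng):
        vals = rng.lognormal(5, 1, size=(20, 6))
        d = sam_statistic(vals, LABELS_3V3, s0=1e12)
        assert np.all(np.abs(d) < 1e-6)

    def test_group_smaller_than_two_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            sam_statistic(np.ones((3, 3)), ["A", "B", "B"], s0=1.0)


class TestEstimateS0:
    def test_all_equal_se_returns_that_value(self):
        # two probes with identical pooled SE and different means
        vals = np.array([[4.0, 6.0, 1.0, 3.0], [14.0, 16.0, 2.0, 4.0]])
        s = pooled_se(vals, ["A", "A", "B", "B"])
        assert np.ptp(s) == 0
        assert estimate_s0(vals, ["A", "A", "B", "B"]) == pytest.approx(s[0])

    def test_within_range_of_se_distribution(self, rng):
        vals = rng.lognormal(5, 1, size=(500, 6))
        s = pooled_se(vals, LABELS_3V3)
        s0 = estimate_s0(vals, LABELS_3V3)
        assert s.min() <= s0 <= s.max()

    def test_deterministic(self, rng):
        vals = rng.lognormal(5, 1, size=(200, 6))
        assert estimate_s0(vals, LABELS_3V3) == estimate_s0(vals, LABELS_3V3)

    def test_degenerate_all_zero_se_floored(self):
        vals = np.tile([[4.0, 4.0, 2.0, 2.0]], (5, 1))
        with pytest.warns(UserWarning, match="zero"):
            s0 = estimate_s0(vals, ["A", "A", "B", "B"])
        assert s0 > 0


def _brute_force_exhaustive_p(vals, n_a, s0):
    """Independent oracle: enumerate C(n, n_a) assignments with plain loops."""
    n = vals.shape[1]
    d_obs = _plain_d(vals, list(range(n_a)), s0)
    ps = []
    for i in range(vals.shape[0]):
        count, total = 0, 0
        for combo in combinations(range(n), n_a):
            total += 1
            if abs(_plain_d(vals, list(combo), s0)[i]) >= abs(d_obs[i]) - 1e-12:
                count += 1
        ps.append(count / total)
    return np.array(ps)


def _plain_d(vals, idx_a, s0):
    idx_b = [j for j in range(vals.shape[1]) if j not in idx_a]
    a, b = vals[:, idx_a], vals[:, idx_b]
    na, nb = len(idx_a), len(idx_b)
    diff = a.mean(1) - b.mean(1)
    pooled = ((a - a.mean(1, keepdims=True)) ** 2).sum(1) + (
        (b - b.mean(1, keepdims=True)) ** 2
    ).sum(1)
    s = np.sqrt((1 / na + 1 / nb) * pooled / (na + nb - 2))
    return diff / (s + s0)


class TestPermutationPvalues:
    def test_exhaustive_3v3_matches_brute_force_enumeration(self, rng):
        vals = rng.lognormal(5, 1, size=(12, 6))
        p, meta = permutation_pvalues(vals, LABELS_3V3, n_perm=1000, s0=0.5)
        assert meta["mode"] == "exhaustive" and meta["n_perm"] == 20
        expected = _brute_force_exhaustive_p(vals, 3, s0=0.5)
        np.testing.assert_allclose(p, expected)
        # p-values are plain counts: multiples of 1/20
        np.testing.assert_allclose(p * 20, np.round(p * 20))

    def test_extreme_probe_attains_minimal_p(self, rng):
        vals = rng.lognormal(5, 0.1, size=(20, 6))
        vals[0, :3] *= 100  # one probe far beyond any permuted value
        p, _ = permutation_pvalues(vals, LABELS_3V3, n_perm=1000, s0=0.1)
        # the observed assignment and its complement both reach |d|, so the
        # minimal attainable exhaustive p at 3v3 is 2/20
        assert p[0] == pytest.approx(2 / 20)
        assert p[0] == p.min()

    def test_exhaustive_mode_independent_of_requested_n_perm(self, rng):
        vals = rng.lognormal(5, 1, size=(15, 6))
        p1, _ = permutation_pvalues(vals, LABELS_3V3, n_perm=20, s0=0.3)
        p2, _ = permutation_pvalues(vals, LABELS_3V3, n_perm=5000, s0=0.3)
        np.testing.assert_array_equal(p1, p2)

    def test_sampled_mode_seeded_and_reproducible(self, rng):
        vals = rng.lognormal(5, 1, size=(10, 12))
        labels = ["A"] * 6 + ["B"] * 6  # C(12,6)=924 > n_perm
        p1, meta = permutation_pvalues(vals, labels, n_perm=200, seed=11, s0=0.3)
        p2, _ = permutation_pvalues(vals, labels, n_perm=200, seed=11, s0=0.3)
        assert meta["mode"] == "sampled"
        np.testing.assert_array_equal(p1, p2)
        with pytest.raises(ValueError, match="seed"):
            permutation_pvalues(vals, labels, n_perm=200, s0=0.3)

    def test_sampled_add_one_convention_bounds(self, rng):
        vals = rng.lognormal(5, 1, size=(10, 12))
        labels = ["A"] * 6 + ["B"] * 6
        p, _ = permutation_pvalues(vals, labels, n_perm=100, seed=1, s0=0.3)
        assert np.all(p >= 1 / 101) and np.all(p <= 1.0)


class TestBhFdr:
    def test_hand_applied_step_up_oracle(self):
        # p=(0.01,0.02,0.03,0.04), m=4: q_i = min_k>=i p_k*4/k = 0.04 for all
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_all_ones(self):
        np.testing.assert_array_equal(bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_q_at_least_p_and_monotone_in_rank(self, ps):
        q = bh_fdr(ps)
        p = np.asarray(ps)
        assert np.all(q >= p - 1e-12)
        assert np.all(q <= 1.0 + 1e-12)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestSamDEModel:
    def test_fit_summary_and_sidecar(self, rng, tmp_path):
        vals = rng.lognormal(5, 0.2, size=(50, 6))
        vals[:5, :3] *= 4
        res = SamDE(vals, LABELS_3V3, probe_ids=[f"g{i}" for i in range(50)]).fit(
            n_perm=1000, seed=3
        )
        tbl = res.summary()
        assert list(tbl.columns) == ["probe_id", "mean_diff", "s", "d", "p", "q"]
        assert np.all((tbl["p"] >= 0) & (tbl["p"] <= 1))
        assert np.all(tbl["q"] >= tbl["p"] - 1e-12)
        # planted probes carry the largest statistics
        assert set(tbl.nlargest(5, "d")["probe_id"]) == {f"g{i}" for i in range(5)}
        res.to_tsv(tmp_path / "de.tsv", sidecar_path=tmp_path / "de.json")
        assert (tmp_path / "de.tsv").exists() and (tmp_path / "de.json").exists()

    def test_from_matrix_selects_lines(self, study_sheet):
        from ohcpipe.simulate import SimulationConfig, simulate_expression

        matrix, sheet, _ = simulate_expression(SimulationConfig(n_probes=50, seed=0))
        model = SamDE.from_matrix(matrix, sheet, "MT1E", "MT1E-CT")
        assert model.values.shape == (50, 6)
        assert list(model.labels[:3]) == ["MT1E"] * 3
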