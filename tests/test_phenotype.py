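from itertools import combinations

import numpy as np
import pytest

from ohcpipe.phenotype import (
    DomeRecord,
    TerRecord,
    combined_daily_mean,
    dome_geneset_association,
    dome_summary,
    ter_filter_value,
    ter_summary,
)
from ohcpipe.simulate import simulate_phenotype


def _flask(counts, flask_id="f1"):
    return DomeRecord(flask_id=flask_id, counts=tuple(counts))


class TestDomeSummary:
    def test_per_field_mean_scales_to_21_fields(self):
        # 21 domes over 10 flasks x 21 fields: mean 0.1/field -> 2.1/21 fields
        records = []
        for f in range(10):
            counts = [0] * 21
            if f < 7:  # 7 flasks carry 3 domes each = 21 domes total
                counts[f] = 3
            records.append(_flask(counts, f"f{f}"))
        summ = dome_summary(records)
        assert summ.mean_per_field == pytest.approx(0.1)
        assert summ.mean_per_21_fields == pytest.approx(2.1)
        assert summ.dome_positive

    def test_all_zero_counts_negative_flag(self):
        summ = dome_summary([_flask([0] * 21)])
        assert summ == type(summ)(0.0, 0.0, False)

    def test_wrong_field_count_rejected(self):
        with pytest.raises(ValueError, match="21"):
            _flask([0] * 20)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            _flask([0] * 20 + [-1])

    def test_per21_exactly_21x_per_field(self, rng):
        for _ in range(20):
            records = [
                _flask(rng.integers(0, 5, size=21), f"f{i}")
                for i in range(int(rng.integers(1, 5)))
            ]
            summ = dome_summary(records)
            assert summ.mean_per_21_fields == 21 * summ.mean_per_field

    def test_poisson_simulated_counts_recover_rate(self):
        records, _, truth = simulate_phenotype(2.7, n_flasks=400, seed=8)
        summ = dome_summary(records)
        assert summ.mean_per_field == pytest.approx(2.7, rel=0.05)
        assert summ.mean_per_21_fields == pytest.approx(56.7, rel=0.05)

    def test_zero_rate_gives_all_zero_counts(self):
        records, _, _ = simulate_phenotype(0.0, n_flasks=5, seed=1)
        assert all(sum(r.counts) == 0 for r in records)


class TestTerSummary:
    def test_filter_value_blank_subtracted_and_area_scaled(self):
        rec = TerRecord("f1", 5, tuple([150.0] * 8), blank_ohm=100.0, area_cm2=4.2)
        assert ter_filter_value(rec) == pytest.approx(50.0 * 4.2)

    def test_three_identical_daily_means_combine_to_same(self):
        records = [
            TerRecord(f"f{i}", day, tuple([130.0] * 8), 100.0, 1.0)
            for day in (5, 6, 7)
            for i in range(3)
        ]
        table = ter_summary(records)
        assert table.attrs["combined"] == pytest.approx(30.0)
        assert (table["mean"] == 30.0).all()

    def test_missing_day_rejected(self):
        records = [TerRecord("f1", 5, tuple([130.0] * 8), 100.0, 1.0)]
        with pytest.raises(ValueError, match="days \\[6, 7\\]"):
            ter_summary(records)

    def test_combined_mean_rounds_half_to_even(self):
        assert combined_daily_mean([41.99, 53.08, 47.67]) == 47.58
        # parent-row style value: 31.136..., half-even rounds to 31.14
        assert combined_daily_mean([38.80, 22.21, 32.40]) == 31.14
        assert combined_daily_mean([0.005, 0.005, 0.005]) == 0.0  # ties to even

    def test_simulated_ter_reproduces_configured_means(self):
        _, records, truth = simulate_phenotype(
            0.0, n_flasks=60, ter_mean=(40.0, 50.0, 45.0), ter_sd=5.0, seed=4
        )
        table = ter_summary(records)
        np.testing.assert_allclose(table["mean"], truth["ter_means"], rtol=0.05)


class TestDomeAssociation:
    FLAGS_3V5 = {l: l in "abc" for l in "abcdefgh"}

    def test_perfect_separation_minimal_exhaustive_p(self):
        expr = dict(zip("abcdefgh", [8.0, 7.0, 6.0, 5.0, 4.0, 3.0, 2.0, 1.0]))
        res = dome_geneset_association(self.FLAGS_3V5, expr)
        assert res.exhaustive and res.n_permutations == 56
        assert res.p_value == pytest.approx(1 / 56)
        # independent enumeration oracle for C(8, 3)
        ranks = {l: expr[l] for l in expr}
        obs = sum(sorted(expr.values(), reverse=True)[:3])
        count = sum(
            1
            for combo in combinations(expr.values(), 3)
            if sum(combo) >= obs
        )
        assert res.p_value == count / 56

    def test_identical_expression_p_near_one(self):
        expr = {l: 1.0 for l in "abcdefgh"}
        res = dome_geneset_association(self.FLAGS_3V5, expr)
        assert res.p_value == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="each phenotype class"):
            dome_geneset_association({"a": True, "b": True}, {"a": 1.0, "b": 2.0})

    def test_mismatched_line_sets_rejected(self):
        with pytest.raises(ValueError, match="same lines"):
            dome_geneset_association({"a": True, "b": False}, {"a": 1.0, "c": 2.0})

    def test_null_p_values_super_uniform(self, rng):
        # no expression-phenotype link: the exact permutation p must be
        # valid, i.e. P(p <= t) <= t (up to Monte-Carlo error); ties in the
        # integer rank-sum make it conservative, never anti-conservative
        ps = np.array([
            dome_geneset_association(
                self.FLAGS_3V5, dict(zip("abcdefgh", rng.normal(size=8)))
            ).p_value
            for _ in range(400)
        ])
        for t in (0.02, 0.05, 0.1, 0.25, 0.5):
            assert np.mean(ps <= t) <= t + 0.05
        assert ps.min() >= 1 / 56 - 1e-12

    def test_synthetic_ct_lines_rank_above_nt_lines(self):
        from ohcpipe.genesets import build_gene_sets
        from ohcpipe.simulate import SimulationConfig, simulate_expression

        matrix, sheet, truth = simulate_expression(SimulationConfig(seed=3))
        block = truth.blocks["gage_like"]
        means = {}
        for line in sheet.cell_lines:
            arrays = sheet.arrays_for_line(line)
            means[line] = float(matrix.values.loc[block, arrays].mean().mean())
        ct_only = [l for l in means if sheet.line_flags(l)[1] and not sheet.line_flags(l)[2]]
        nt = [l for l in means if sheet.line_flags(l)[2]]
        assert min(means[l] for l in ct_only) > max(means[l] for l in nt)
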