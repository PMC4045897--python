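"""Reference-population rules, inclusion threshold, metrics and ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from closedcmr import (
    EstimateResult,
    SimulationConfig,
    build_reference,
    capture_frequencies,
    ci_coverage_and_width,
    p_threshold,
    performance_metrics,
    rank_estimators,
    restrict_to_period,
    simulate_robust_design,
)
from closedcmr.datasets import gecko_metadata, load_gecko_reported


class TestPThreshold:
    @pytest.mark.parametrize("n,expected", [(10, 0.259), (5, 0.451), (1, 0.95)])
    def test_key_values(self, n, expected):
        assert p_threshold(n) == pytest.approx(expected, abs=5e-4)

    @pytest.mark.parametrize("mode", ["partly", "fully"])
    def test_reproduces_study_thresholds(self, mode):
        meta = gecko_metadata(mode)
        for _, row in meta.iterrows():
            assert p_threshold(int(row["n_occ_ref"])) == pytest.approx(
                row["p_tr"], abs=5e-4
            )

    def test_strictly_decreasing_and_vanishing(self):
        vals = [p_threshold(n) for n in range(1, 200)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert p_threshold(10_000) < 1e-3

    def test_rejects_zero(self):
        with pytest.raises(ValueError):
            p_threshold(0)


class TestBuildReference:
    def test_rule_by_rule_on_toy(self, three_periods):
        # X caught only P1, Y in P1+P3, W everywhere, Z juvenile born P3
        ref_p, est_p = build_reference(three_periods, "P1", "partly")
        assert set(ref_p.members) == {"X", "Y", "W"}
        assert "Z" not in ref_p.members  # unborn juvenile excluded
        assert est_p.individuals == restrict_to_period(three_periods, "P1").individuals

        ref_f, est_f = build_reference(three_periods, "P1", "fully")
        assert set(ref_f.members) == {"Y", "W"}   # X dropped: P1-only
        assert "X" not in est_f.individuals        # and removed from data

    def test_fully_subset_of_partly(self, three_periods):
        for period in ("P1", "P2"):
            ref_p, _ = build_reference(three_periods, period, "partly")
            ref_f, _ = build_reference(three_periods, period, "fully")
            assert ref_f.members <= ref_p.members

    def test_ever_present_animal_in_every_reference(self, three_periods):
        for period in ("P1", "P2"):
            for mode in ("partly", "fully"):
                ref, _ = build_reference(three_periods, period, mode)
                assert "W" in ref.members

    def test_last_period_refused(self, three_periods):
        with pytest.raises(ValueError, match="last primary period"):
            build_reference(three_periods, "P3", "partly")

    def test_occasion_counts_drive_threshold(self, three_periods):
        ref_p, _ = build_reference(three_periods, "P1", "partly")
        ref_f, _ = build_reference(three_periods, "P1", "fully")
        assert ref_p.n_occ == 6 and ref_f.n_occ == 4
        assert ref_p.p_tr == pytest.approx(p_threshold(6))

    def test_high_capture_simulation_matches_truth(self):
        """At near-certain detection the partly reference equals the
        simulator's exposed population for early periods."""
        data, truth = simulate_robust_design(
            SimulationConfig(N0=60, periods=3, occasions=4,
                             heterogeneity=("constant", 0.95), survival=0.8,
                             recruitment=10, seed=99)
        )
        for period in ("P1", "P2"):
            ref, _ = build_reference(data, period, "partly")
            assert set(ref.members) == set(truth.alive[period])

    def test_per_period_S_matches_simulator_bookkeeping(self):
        data, truth = simulate_robust_design(
            SimulationConfig(N0=50, periods=3, occasions=5,
                             heterogeneity=("constant", 0.9), survival=0.9,
                             recruitment=5, seed=123)
        )
        for period in data.primary_periods:
            sub = restrict_to_period(data, period)
            caught = {
                i for i, row in zip(data.individuals, data.matrix)
                if row[[data.occasions.index(o)
                        for o in data.occasions_of(period)]].any()
            }
            assert capture_frequencies(sub).S == len(caught)


def _res(n_hat, lo=None, hi=None):
    lo = n_hat if lo is None else lo
    hi = n_hat if hi is None else hi
    return EstimateResult(n_hat=n_hat, se=0.0, ci_low=lo, ci_high=hi, method="x")


class TestPerformanceMetrics:
    def test_perfect_estimator(self):
        perf = performance_metrics([100.0, 100.0], [100, 100])
        assert perf.rel_bias == perf.rel_precision == perf.rel_accuracy == 0.0

    def test_hand_arithmetic(self):
        perf = performance_metrics([110.0, 90.0], [100, 100])
        assert perf.rel_bias == pytest.approx(0.0)
        assert perf.rel_precision == pytest.approx(0.01)
        assert perf.rel_accuracy == pytest.approx(0.01)

    def test_mlp_bias_on_reported_fully_estimates(self):
        rep = load_gecko_reported("fully")
        meta = gecko_metadata("fully")
        row = rep[rep.estimator == "MLP"].set_index("period")
        ests = [row.loc[p, "estimate"] for p in meta.index]
        refs = [meta.loc[p, "N_ref"] for p in meta.index]
        perf = performance_metrics(ests, refs)
        assert perf.rel_bias == pytest.approx(-0.117, abs=1e-3)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="references"):
            performance_metrics([1.0], [1, 2])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.floats(10, 500), st.integers(10, 500)),
                    min_size=1, max_size=8))
    def test_mse_decomposition(self, pairs):
        ests = [e for e, _ in pairs]
        refs = [r for _, r in pairs]
        perf = performance_metrics(ests, refs)
        assert perf.rel_accuracy == pytest.approx(
            perf.rel_precision + perf.rel_bias**2, abs=1e-12, rel=1e-9
        )


class TestCoverageAndWidth:
    def test_me_row_coverage_and_width(self):
        rep = load_gecko_reported("partly")
        meta = gecko_metadata("partly")
        row = rep[rep.estimator == "ME"].set_index("period")
        ests = [_res(row.loc[p, "estimate"], row.loc[p, "ci_low"],
                     row.loc[p, "ci_high"]) for p in meta.index]
        refs = [meta.loc[p, "N_ref"] for p in meta.index]
        count, width = ci_coverage_and_width(ests, refs)
        assert count == 5
        assert width == pytest.approx(np.mean([113, 73, 72, 68, 66]))  # 78.4

    def test_degenerate_ci_not_covered(self):
        count, _ = ci_coverage_and_width([_res(50.0)], [60])
        assert count == 0

    def test_missing_ci_skipped_with_warning(self):
        good = _res(100.0, 90.0, 110.0)
        bad = EstimateResult(n_hat=100.0, se=float("nan"),
                             ci_low=float("nan"), ci_high=float("nan"),
                             method="x")
        with pytest.warns(UserWarning, match="skipped"):
            count, width = ci_coverage_and_width([good, bad], [100, 100])
        assert count == 1
        assert width == pytest.approx(20.0)


class TestRanking:
    def test_two_estimators_flagging(self):
        summaries = {
            "good": performance_metrics([101.0, 99.0], [100, 100]),
            "bad": performance_metrics([110.0, 111.0], [100, 100]),
        }
        table = rank_estimators(summaries)
        assert table.loc["good", "rel_bias_rank"] == 1
        assert table.loc["bad", "rel_bias_rank"] == 2
        assert bool(table.loc["good", "rel_bias_top"])
        assert not bool(table.loc["bad", "rel_bias_top"])

    def test_identical_values_tie(self):
        summaries = {
            "b": performance_metrics([110.0], [100]),
            "a": performance_metrics([110.0], [100]),
        }
        table = rank_estimators(summaries)
        assert table["rel_bias_rank"].tolist() == [1, 1]
        assert table.index.tolist() == ["a", "b"]  # stable label order

    def test_mlp_ranks_first_on_bias_among_petersen_family(self):
        rep = load_gecko_reported("fully")
        meta = gecko_metadata("fully")
        refs = [meta.loc[p, "N_ref"] for p in meta.index]
        summaries = {}
        for name in ("MLP", "SC1", "MPE", "IntJK"):
            row = rep[rep.estimator == name].set_index("period")
            ests = [row.loc[p, "estimate"] for p in meta.index]
            summaries[name] = performance_metrics(ests, refs, label=name)
        table = rank_estimators(summaries)
        assert table.loc["MLP", "rel_bias_rank"] == 1

    def test_single_estimator_rejected(self):
        with pytest.raises(ValueError, match="at least two"):
            rank_estimators({"x": performance_metrics([1.0], [1])})
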