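"""Finite-mixture and Huggins conditional-likelihood models with AIC selection."""

import numpy as np
import pytest
from scipy import special

from closedcmr import (
    CaptureData,
    SimulationConfig,
    capture_frequencies,
    finite_mixture_fit,
    huggins_ht_fit,
    select_huggins_aic,
    select_mixture_aic,
    simulate_robust_design,
)


def _m0_grid_mle(data):
    """Independent oracle: integer-N grid search of the M0 likelihood."""
    fq = capture_frequencies(data)
    S, n, t = fq.S, fq.n, fq.t

    def loglik(N):
        p = n / (N * t)
        return float(
            special.gammaln(N + 1) - special.gammaln(N - S + 1)
            + n * np.log(p) + (N * t - n) * np.log1p(-p)
        )

    grid = np.arange(S, 4 * S)
    return int(grid[np.argmax([loglik(N) for N in grid])])


class TestFiniteMixture:
    def test_g1_matches_grid_search_oracle(self):
        data, _ = simulate_robust_design(
            SimulationConfig(N0=80, occasions=5,
                             heterogeneity=("constant", 0.35), seed=11)
        )
        res = finite_mixture_fit(data, G=1, seed=0)
        oracle = _m0_grid_mle(data)
        assert abs(res.n_hat - oracle) <= 1.0
        assert res.ci_low <= oracle <= res.ci_high  # profile CI holds the MLE

    def test_all_caught_every_occasion(self, all_caught):
        res = finite_mixture_fit(all_caught, G=1, seed=0, compute_ci=False)
        assert res.n_hat == pytest.approx(10.0, abs=0.01)
        assert res.diagnostics["p"][0] == pytest.approx(1.0, abs=0.01)

    def test_g2_likelihood_never_below_g1(self):
        data, _ = simulate_robust_design(
            SimulationConfig(N0=150, occasions=8,
                             heterogeneity=("beta", 1, 3), seed=21)
        )
        ll1 = finite_mixture_fit(data, G=1, seed=0,
                                 compute_ci=False).diagnostics["loglik"]
        ll2 = finite_mixture_fit(data, G=2, seed=0,
                                 compute_ci=False).diagnostics["loglik"]
        assert ll2 >= ll1 - 1e-4

    def test_aic_prefers_g2_on_two_point_mixture(self):
        wins, reps = 0, 15
        for s in range(reps):
            data, _ = simulate_robust_design(
                SimulationConfig(N0=300, occasions=10,
                                 heterogeneity=("mixture", 0.5, 0.05, 0.4),
                                 seed=6000 + s)
            )
            a1 = finite_mixture_fit(data, G=1, seed=s,
                                    compute_ci=False).diagnostics["aic"]
            a2 = finite_mixture_fit(data, G=2, seed=s,
                                    compute_ci=False).diagnostics["aic"]
            wins += a2 < a1
        assert wins / reps >= 0.8

    def test_aic_prefers_m0_on_homogeneous_data(self):
        wins, reps = 0, 15
        for s in range(reps):
            data, _ = simulate_robust_design(
                SimulationConfig(N0=200, occasions=8,
                                 heterogeneity=("constant", 0.3), seed=7000 + s)
            )
            res = select_mixture_aic(data, [(1, False, False), (2, False, False)],
                                     seed=s)
            wins += res.diagnostics["G"] == 1
        assert wins / reps >= 0.8

    def test_single_candidate_is_identity(self):
        data, _ = simulate_robust_design(
            SimulationConfig(N0=60, occasions=5,
                             heterogeneity=("constant", 0.4), seed=2)
        )
        res = select_mixture_aic(data, [(1, False, False)], seed=0)
        direct = finite_mixture_fit(data, G=1, seed=0)
        assert res.n_hat == pytest.approx(direct.n_hat, rel=1e-6)

    def test_invalid_G_rejected(self, toy):
        with pytest.raises(ValueError, match="G must be"):
            finite_mixture_fit(toy, G=4)


class TestHuggins:
    def test_intercept_only_forced_arithmetic(self):
        """Horvitz-Thompson arithmetic at a fixed p = 0.5, t = 2, S = 30:
        p* = 1 - 0.5^2 = 0.75 and N = 30 / 0.75 = 40."""
        m = np.vstack([
            np.tile([1, 1], (10, 1)),
            np.tile([1, 0], (10, 1)),
            np.tile([0, 1], (10, 1)),
        ])
        data = CaptureData([f"i{k}" for k in range(30)], ["1", "2"], m)
        from closedcmr.likelihood import HugginsHT

        model = HugginsHT(data, "~ 1")
        assert model._ht_of(np.zeros(1)) == pytest.approx(40.0)  # logit 0 = p 0.5

    def test_all_caught_gives_S(self, all_caught):
        res = huggins_ht_fit(all_caught, "~ 1")
        assert res.n_hat == pytest.approx(10.0, abs=0.05)

    def test_missing_covariate_rejected(self, toy):
        with pytest.raises(ValueError, match="missing covariate"):
            huggins_ht_fit(toy, "~ hut")

    def test_covariate_model_less_biased_than_intercept_only(self):
        bias_cov, bias_m0 = [], []
        for s in range(25):
            data, _ = simulate_robust_design(
                SimulationConfig(N0=200, occasions=8,
                                 heterogeneity=("constant", 0.25),
                                 sites={"A": 0.4, "B": 1.6}, seed=8000 + s)
            )
            bias_cov.append(huggins_ht_fit(data, "~ site").n_hat - 200)
            bias_m0.append(huggins_ht_fit(data, "~ 1").n_hat - 200)
        assert abs(np.mean(bias_cov)) < abs(np.mean(bias_m0))

    def test_ht_invariant_to_covariate_relabeling(self):
        data, _ = simulate_robust_design(
            SimulationConfig(N0=120, occasions=6,
                             heterogeneity=("constant", 0.3),
                             sites={"A": 0.6, "B": 1.4}, seed=31)
        )
        res1 = huggins_ht_fit(data, "~ site")
        relabeled = CaptureData(
            individuals=data.individuals,
            occasions=data.occasions,
            matrix=data.matrix,
            primary_of=data.primary_of,
            covariates=data.covariates.assign(
                site=data.covariates["site"].map({"A": "Z_hi", "B": "B_lo"})
            ),
            birth_period=data.birth_period,
        )
        res2 = huggins_ht_fit(relabeled, "~ site")
        assert res1.n_hat == pytest.approx(res2.n_hat, rel=1e-5)

    def test_aic_selects_time_model_under_occasion_effects(self):
        wins, reps = 0, 15
        for s in range(reps):
            data, _ = simulate_robust_design(
                SimulationConfig(N0=150, occasions=6,
                                 heterogeneity=("constant", 0.3),
                                 time_effects=[1.5, 0.4, 1.2, 0.5, 1.4, 0.6],
                                 seed=9000 + s)
            )
            sel = select_huggins_aic(data, {"M0": "~ 1", "Mt": "~ time"})
            wins += sel.diagnostics["selected"] == "Mt"
        assert wins / reps >= 0.8

    def test_aic_selects_m0_on_homogeneous_data(self):
        wins, reps = 0, 15
        for s in range(reps):
            data, _ = simulate_robust_design(
                SimulationConfig(N0=150, occasions=6,
                                 heterogeneity=("constant", 0.3), seed=9500 + s)
            )
            sel = select_huggins_aic(data, {"M0": "~ 1", "Mt": "~ time"})
            wins += sel.diagnostics["selected"] == "M0"
        assert wins / reps >= 0.8

    def test_single_candidate_identity(self):
        data, _ = simulate_robust_design(
            SimulationConfig(N0=80, occasions=5,
                             heterogeneity=("constant", 0.35), seed=41)
        )
        sel = select_huggins_aic(data, {"M0": "~ 1"})
        assert sel.diagnostics["selected"] == "M0"
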