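"""Estimators driven purely by capture frequencies.

Three classical closed-population heterogeneity (Mh) estimators that consume
only the frequency vector f_1..f_t:

* Chao's moment estimator, N-hat = S + f1^2 / (2 f2) — a lower bound for the
  population size under individual heterogeneity, built from the singleton
  and doubleton counts.
* The Burnham-Overton jackknife (orders 1-5), linear combinations of all
  capture frequencies, with the sequential order-selection test and
  interpolation used by program CAPTURE.
* A zero-truncated geometric fit: capture counts are modelled as a geometric
  distribution right-truncated at the occasion count, and abundance follows
  from the fitted probability of being caught at least once.  In the
  untruncated limit the estimate has the closed form N-hat = S n / (n - S).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats

from .base import Z95, AbundanceModel, EstimateResult, lognormal_ci
from .data import FrequencyData

__all__ = [
    "ChaoMoment",
    "InterpolatedJackknife",
    "TruncatedGeometric",
    "GeometricFit",
    "chao_moment",
    "jackknife_interpolated",
    "trunc_geom_fit",
]


# -- Chao moment estimator -------------------------------------------------


class ChaoMoment(AbundanceModel):
    """Chao's moment (lower-bound) estimator from singletons and doubletons."""

    method = "ME"

    def __init__(self, freq: FrequencyData):
        self.freq = freq

    def fit(self) -> EstimateResult:
        f = self.freq.f
        S = self.freq.S
        f1 = float(f[0]) if len(f) >= 1 else 0.0
        f2 = float(f[1]) if len(f) >= 2 else 0.0
        if f1 == 0:
            n_hat, var = float(S), 0.0
        elif f2 > 0:
            n_hat = S + f1**2 / (2 * f2)
            r = f1 / f2
            var = f2 * (r**4 / 4 + r**3 + r**2 / 2)
        else:
            # bias-corrected fallback when no doubletons were observed
            n_hat = S + f1 * (f1 - 1) / 2
            var = (
                f1 * (f1 - 1) / 2
                + f1 * (2 * f1 - 1) ** 2 / 4
                - f1**4 / (4 * n_hat)
            )
        lo, hi = lognormal_ci(S, n_hat, var)
        return EstimateResult(
            n_hat=n_hat,
            se=float(np.sqrt(max(var, 0.0))),
            ci_low=lo,
            ci_high=hi,
            method=self.method,
            diagnostics={"f1": f1, "f2": f2, "S": S},
        )


def chao_moment(freq: FrequencyData) -> EstimateResult:
    return ChaoMoment(freq).fit()


# -- Burnham-Overton interpolated jackknife --------------------------------


def _jackknife_coefficients(t: int, max_order: int) -> np.ndarray:
    """Total coefficients a[k, j] with N-hat_k = sum_j a[k, j] f_{j+1}.

    Row k (1-based order) holds the order-k coefficients; entries beyond the
    order are 1 (those frequencies enter only through S).
    """
    a = np.ones((max_order + 1, t))  # row 0 = S itself
    T = float(t)

    def setrow(k: int, coefs: list[float]) -> None:
        for j, c in enumerate(coefs):
            a[k, j] = 1.0 + c

    if max_order >= 1:
        setrow(1, [(T - 1) / T])
    if max_order >= 2:
        setrow(2, [(2 * T - 3) / T, -((T - 2) ** 2) / (T * (T - 1))])
    if max_order >= 3:
        setrow(3, [
            (3 * T - 6) / T,
            -(3 * T**2 - 15 * T + 19) / (T * (T - 1)),
            (T - 3) ** 3 / (T * (T - 1) * (T - 2)),
        ])
    if max_order >= 4:
        setrow(4, [
            (4 * T - 10) / T,
            -(6 * T**2 - 36 * T + 55) / (T * (T - 1)),
            (4 * T**3 - 42 * T**2 + 148 * T - 175) / (T * (T - 1) * (T - 2)),
            -((T - 4) ** 4) / (T * (T - 1) * (T - 2) * (T - 3)),
        ])
    if max_order >= 5:
        setrow(5, [
            (5 * T - 15) / T,
            -(10 * T**2 - 70 * T + 125) / (T * (T - 1)),
            (10 * T**3 - 120 * T**2 + 485 * T - 660) / (T * (T - 1) * (T - 2)),
            -((T - 4) ** 5 - (T - 5) ** 5) / (T * (T - 1) * (T - 2) * (T - 3)),
            (T - 5) ** 5 / (T * (T - 1) * (T - 2) * (T - 3) * (T - 4)),
        ])
    return a


class InterpolatedJackknife(AbundanceModel):
    """Jackknife estimator with CAPTURE-style order selection.

    Orders 1..min(5, t-1) are computed; successive differences are tested
    (two-sided normal, alpha = 0.05) and the estimate interpolates between
    the highest supported order m and m+1 with weight |z_m| / z_crit, so a
    difference just short of significance leans toward the higher order.
    """

    method = "IntJK"

    def __init__(self, freq: FrequencyData, alpha: float = 0.05):
        freq.require_occasions("jackknife")
        if freq.t < 2:
            raise ValueError("jackknife needs at least two occasions")
        self.freq = freq
        self.alpha = alpha

    def order_estimates(self) -> np.ndarray:
        """Point estimates for orders 1..min(5, t-1)."""
        t = self.freq.t
        K = min(5, t - 1)
        a = _jackknife_coefficients(t, K)
        return a[1:] @ self.freq.f

    def fit(self) -> EstimateResult:
        freq, t = self.freq, self.freq.t
        f = freq.f.astype(float)
        S = freq.S
        K = min(5, t - 1)
        a = _jackknife_coefficients(t, K)
        n_hats = a @ f  # index 0 is S itself
        variances = np.maximum((a**2) @ f - n_hats, 0.0)
        zcrit = stats.norm.ppf(1 - self.alpha / 2)

        z_stats = np.full(K, np.inf)
        for k in range(1, K):
            d = n_hats[k + 1] - n_hats[k]
            b = a[k + 1] - a[k]
            var_d = (S / max(S - 1, 1)) * ((b**2) @ f - d**2 / max(S, 1))
            z_stats[k] = abs(d) / math.sqrt(var_d) if var_d > 0 else 0.0

        sel = next((k for k in range(1, K) if z_stats[k] < zcrit), None)
        if sel is None:  # every difference significant (or K == 1)
            order, weight = K, 0.0
            coef = a[K]
            n_hat = float(n_hats[K])
        else:
            order = sel
            weight = float(z_stats[sel] / zcrit)
            coef = (1 - weight) * a[sel] + weight * a[sel + 1]
            n_hat = float(coef @ f)
        # a population estimate cannot fall below the number of animals seen
        n_hat = max(n_hat, float(S))
        var = float(max((coef**2) @ f - n_hat, 0.0))
        se = math.sqrt(var)
        lo, hi = lognormal_ci(S, n_hat, var)
        return EstimateResult(
            n_hat=n_hat,
            se=se,
            ci_low=lo,
            ci_high=hi,
            method=self.method,
            diagnostics={
                "order": order,
                "interp_weight": weight,
                "order_estimates": n_hats[1:].tolist(),
                "order_se": np.sqrt(variances[1:]).tolist(),
                "z_stats": z_stats[1:].tolist(),
            },
        )


def jackknife_interpolated(freq: FrequencyData) -> EstimateResult:
    return InterpolatedJackknife(freq).fit()


# -- truncated geometric ---------------------------------------------------


@dataclass
class GeometricFit:
    """Fitted geometric success parameter with its maximized log-likelihood."""

    q_hat: float
    loglik: float
    truncation: float

    def __post_init__(self) -> None:
        if not 0 < self.q_hat < 1:
            raise ValueError("q must lie strictly in (0, 1)")


def _geom_cond_loglik(q: float, S: int, n: int, t: float) -> float:
    # zero-truncated, right-truncated-at-t geometric: P(j) = (1-q) q^(j-1) / (1-q^t)
    ll = (n - S) * math.log(q) + S * math.log1p(-q)
    if math.isfinite(t):
        ll -= S * math.log1p(-(q**t))
    return ll


def _geom_full_loglik(N: float, q: float, S: int, n: int, t: float) -> float:
    # unconditional likelihood over support {0..t}: P(X=j) = (1-q) q^j / (1-q^(t+1))
    if N < S or not 0 < q < 1:
        return -np.inf
    logP0 = math.log1p(-q)
    norm = 0.0
    if math.isfinite(t):
        norm = math.log1p(-(q ** (t + 1)))
    ll = (
        special.gammaln(N + 1)
        - special.gammaln(N - S + 1)
        + (N - S) * (logP0 - norm)
        + S * math.log1p(-q)
        + n * math.log(q)
        - S * norm
    )
    return float(ll)


class TruncatedGeometric(AbundanceModel):
    """Abundance from a zero-truncated, right-truncated geometric count fit.

    Requires more than one capture per animal on average (n > S); with all
    singletons the success parameter degenerates to zero and N is unbounded.
    The confidence interval is a chi-square(1) profile-likelihood interval on
    N under the unconditional likelihood.
    """

    method = "TruncGeom"

    def __init__(self, freq: FrequencyData, truncation: float | None = None,
                 compute_ci: bool = True):
        if freq.S < 2:
            raise ValueError("truncated geometric fit needs S >= 2")
        if freq.n <= freq.S:
            raise ValueError(
                "degenerate: all singletons (n = S), q-hat -> 0, N unbounded"
            )
        if truncation is None:
            truncation = float(freq.t) if freq.t is not None else math.inf
        if math.isfinite(truncation):
            kmax = int(np.max(np.nonzero(freq.f)[0])) + 1
            if truncation < kmax:
                raise ValueError(
                    f"truncation {truncation} below max observed frequency {kmax}"
                )
        self.freq = freq
        self.truncation = float(truncation)
        self.compute_ci = compute_ci

    def _qhat(self) -> float:
        S, n, t = self.freq.S, self.freq.n, self.truncation
        if not math.isfinite(t):
            return (n - S) / n
        res = optimize.minimize_scalar(
            lambda q: -_geom_cond_loglik(q, S, n, t),
            bounds=(1e-10, 1 - 1e-10),
            method="bounded",
            options={"xatol": 1e-10},
        )
        return float(res.x)

    def fit(self) -> EstimateResult:
        S, n, t = self.freq.S, self.freq.n, self.truncation
        q = self._qhat()
        if math.isfinite(t):
            p_seen = (q - q ** (t + 1)) / (1 - q ** (t + 1))
        else:
            p_seen = q
        n_hat = S / p_seen
        geom = GeometricFit(q_hat=q, loglik=_geom_cond_loglik(q, S, n, t),
                            truncation=t)

        def profile(N: float) -> float:
            res = optimize.minimize_scalar(
                lambda qq: -_geom_full_loglik(N, qq, S, n, t),
                bounds=(1e-10, 1 - 1e-10),
                method="bounded",
                options={"xatol": 1e-9},
            )
            return -res.fun

        if not self.compute_ci:
            return EstimateResult(
                n_hat=n_hat, se=float("nan"), ci_low=float("nan"),
                ci_high=float("nan"), method=self.method,
                diagnostics={"geometric_fit": geom},
            )

        # maximize the profile around the HT-style point estimate
        grid_hi = max(2 * n_hat - S, S + 2)
        res = optimize.minimize_scalar(
            lambda N: -profile(N), bounds=(S, grid_hi), method="bounded",
            options={"xatol": 1e-6},
        )
        N_mle, ll_max = float(res.x), -float(res.fun)
        cut = ll_max - stats.chi2.ppf(0.95, df=1) / 2

        def g(N: float) -> float:
            return profile(N) - cut

        lo = S if g(S) >= 0 else optimize.brentq(g, S, N_mle, xtol=1e-6)
        hi_bracket = N_mle
        step = max(N_mle - S, 1.0)
        while g(hi_bracket) >= 0 and hi_bracket < 1e7:
            hi_bracket += step
            step *= 2
        hi = (
            float("inf")
            if hi_bracket >= 1e7
            else optimize.brentq(g, max(N_mle, S + 1e-9), hi_bracket, xtol=1e-6)
        )
        # curvature-based SE from the profile log-likelihood
        h = max(1.0, 0.01 * (N_mle - S + 1))
        d2 = (profile(N_mle + h) - 2 * ll_max + profile(N_mle - h)) / h**2
        se = math.sqrt(-1 / d2) if d2 < 0 else (hi - lo) / (2 * Z95)
        lo = min(lo, n_hat)
        hi = max(hi, n_hat)
        return EstimateResult(
            n_hat=n_hat,
            se=se,
            ci_low=float(lo),
            ci_high=float(hi),
            method=self.method,
            diagnostics={"geometric_fit": geom, "N_profile_mle": N_mle},
        )


def trunc_geom_fit(freq: FrequencyData, truncation: float | None = None,
                   compute_ci: bool = True) -> EstimateResult:
    return TruncatedGeometric(freq, truncation=truncation,
                              compute_ci=compute_ci).fit()
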