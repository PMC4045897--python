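"""Sample-coverage (Lee-Chao) machinery and the estimating-equation Mh fit.

The sample coverage C is the probability mass of individual capture
probabilities represented among captured animals, estimated by
C-hat = 1 - f1/n.  The squared coefficient of variation of individual
catchability,

    gamma^2 = max{ (S / C-hat) * sum_k k(k-1) f_k / (2 sum_{j<k} n_j n_k) - 1, 0 },

is zero if and only if individuals are equally catchable, and drives the
heterogeneity correction of the coverage estimators:

    SC1: N-hat = S/C-hat + f1 * gamma^2 / C-hat
    SC2: as SC1 with the bias-corrected coverage C2 = 1 - [f1 - 2 f2/(t-1)]/n.

The estimating-equation (EE) Mh variant solves the same relation
self-consistently, updating gamma^2 with the current abundance instead of
S/C-hat until the fixed point converges.

Standard errors use the asymptotic delta method over the frequency vector
with multinomial covariance cov(f_i, f_j) = f_i (delta_ij - f_j / N-hat),
holding the pairwise effort term fixed, and log-normal intervals on
N-hat - S.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .base import AbundanceModel, EstimateResult, lognormal_ci
from .data import CaptureData, FrequencyData, capture_frequencies

__all__ = [
    "CoverageStats",
    "sample_coverage",
    "SampleCoverage1",
    "SampleCoverage2",
    "EstimatingEquationMh",
    "sc1",
    "sc2",
    "ee_mh",
]


@dataclass
class CoverageStats:
    """Estimated sample coverage and individual-catchability CV."""

    C_hat: float
    gamma_sq: float
    pair_sum: float

    def __post_init__(self) -> None:
        if not 0 <= self.C_hat <= 1:
            raise ValueError(f"coverage must lie in [0, 1], got {self.C_hat}")
        if self.gamma_sq < 0:
            raise ValueError("gamma^2 must be non-negative")

    @property
    def cv(self) -> float:
        return math.sqrt(self.gamma_sq)


def _pair_sum(n_j: np.ndarray) -> float:
    total = float(n_j.sum())
    return (total**2 - float((n_j.astype(float) ** 2).sum())) / 2


def _gamma_sq(first_moment: float, f: np.ndarray, pair_sum: float) -> float:
    k = np.arange(1, len(f) + 1)
    num = float((k * (k - 1) * f).sum())
    if pair_sum <= 0:
        return 0.0
    return max(first_moment * num / (2 * pair_sum) - 1, 0.0)


def sample_coverage(freq: FrequencyData) -> CoverageStats:
    """Coverage C-hat = 1 - f1/n and the CV of individual catchability."""
    freq.require_sample_sizes("sample coverage")
    if freq.n <= 0:
        raise ValueError("no captures")
    f1 = float(freq.f[0])
    C_hat = 1 - f1 / freq.n
    ps = _pair_sum(freq.n_j)
    gsq = _gamma_sq(freq.S / C_hat, freq.f, ps) if C_hat > 0 else 0.0
    return CoverageStats(C_hat=C_hat, gamma_sq=gsq, pair_sum=ps)


def _delta_method_var(freq: FrequencyData, point: Callable[[np.ndarray], float],
                      n_hat: float) -> float:
    """Asymptotic variance of a frequency functional under multinomial sampling."""
    f = freq.f.astype(float)
    grad = np.zeros_like(f)
    for j in range(len(f)):
        h = max(1e-4, 1e-4 * f[j])
        fp, fm = f.copy(), f.copy()
        fp[j] += h
        fm[j] = max(fm[j] - h, 0.0)
        grad[j] = (point(fp) - point(fm)) / (fp[j] - fm[j])
    cov = np.diag(f) - np.outer(f, f) / n_hat
    return float(grad @ cov @ grad)


class SampleCoverage1(AbundanceModel):
    """First Lee-Chao sample-coverage estimator (SC1)."""

    method = "SC1"

    def __init__(self, freq: FrequencyData):
        freq.require_sample_sizes("SC1")
        self.freq = freq

    def _point(self, f: np.ndarray, pair_sum: float) -> float:
        S = float(f.sum())
        k = np.arange(1, len(f) + 1)
        n = float((k * f).sum())
        C = 1 - f[0] / n
        if C <= 0:
            raise ValueError("coverage is zero: every animal a singleton")
        gsq = _gamma_sq(S / C, f, pair_sum)
        return S / C + f[0] * gsq / C

    def fit(self) -> EstimateResult:
        freq = self.freq
        stats_ = sample_coverage(freq)
        if stats_.C_hat <= 0:
            raise ValueError("coverage is zero: every animal a singleton")
        ps = stats_.pair_sum
        n_hat = self._point(freq.f.astype(float), ps)
        var = _delta_method_var(freq, lambda f: self._point(f, ps), n_hat)
        lo, hi = lognormal_ci(freq.S, n_hat, var)
        return EstimateResult(
            n_hat=n_hat,
            se=math.sqrt(max(var, 0.0)),
            ci_low=lo,
            ci_high=hi,
            method=self.method,
            diagnostics={"C_hat": stats_.C_hat, "gamma_sq": stats_.gamma_sq,
                         "cv": stats_.cv},
        )


class SampleCoverage2(AbundanceModel):
    """Bias-corrected sample-coverage estimator (SC2)."""

    method = "SC2"

    def __init__(self, freq: FrequencyData):
        freq.require_sample_sizes("SC2")
        freq.require_occasions("SC2")
        if freq.t < 2:
            raise ValueError("SC2 needs at least two occasions")
        self.freq = freq

    def _coverage2(self, f: np.ndarray) -> float:
        k = np.arange(1, len(f) + 1)
        n = float((k * f).sum())
        f2 = f[1] if len(f) > 1 else 0.0
        return 1 - (f[0] - 2 * f2 / (self.freq.t - 1)) / n

    def _point(self, f: np.ndarray, pair_sum: float) -> float:
        S = float(f.sum())
        C2 = min(self._coverage2(f), 1.0)
        if C2 <= 0:
            raise ValueError(
                f"bias-corrected coverage is non-positive (C2 = {C2:.4f})"
            )
        gsq = _gamma_sq(S / C2, f, pair_sum)
        return S / C2 + f[0] * gsq / C2

    def fit(self) -> EstimateResult:
        freq = self.freq
        ps = _pair_sum(freq.n_j)
        f = freq.f.astype(float)
        C2 = min(self._coverage2(f), 1.0)
        n_hat = self._point(f, ps)
        gsq = _gamma_sq(freq.S / C2, f, ps) if C2 > 0 else 0.0
        var = _delta_method_var(freq, lambda ff: self._point(ff, ps), n_hat)
        lo, hi = lognormal_ci(freq.S, n_hat, var)
        return EstimateResult(
            n_hat=n_hat,
            se=math.sqrt(max(var, 0.0)),
            ci_low=lo,
            ci_high=hi,
            method=self.method,
            diagnostics={"C2_hat": C2, "gamma_sq": gsq, "cv": math.sqrt(gsq)},
        )


class EstimatingEquationMh(AbundanceModel):
    """Estimating-equation Mh: coverage relation solved self-consistently.

    Iterates N <- S/C-hat + (f1/C-hat) * gamma^2(N) where gamma^2 uses the
    current N as the abundance in the CV quadratic form; convergence when the
    relative step falls below 1e-8 (at most 500 iterations — non-convergence
    is flagged in the diagnostics, never silent).
    """

    method = "EE"

    max_iter = 500
    rtol = 1e-8

    def __init__(self, data: CaptureData | FrequencyData):
        freq = capture_frequencies(data) if isinstance(data, CaptureData) else data
        freq.require_sample_sizes("estimating-equation Mh")
        self.freq = freq

    def _solve(self, f: np.ndarray, pair_sum: float) -> tuple[float, bool, int]:
        S = float(f.sum())
        k = np.arange(1, len(f) + 1)
        n = float((k * f).sum())
        C = 1 - f[0] / n
        if C <= 0:
            raise ValueError("coverage is zero: every animal a singleton")
        N = S / C
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            gsq = _gamma_sq(N, f, pair_sum)
            N_new = S / C + f[0] * gsq / C
            if abs(N_new - N) <= self.rtol * max(N, 1.0):
                N = N_new
                converged = True
                break
            N = N_new
        return N, converged, it

    def fit(self) -> EstimateResult:
        freq = self.freq
        ps = _pair_sum(freq.n_j)
        f = freq.f.astype(float)
        n_hat, converged, iters = self._solve(f, ps)
        var = _delta_method_var(freq, lambda ff: self._solve(ff, ps)[0], n_hat)
        lo, hi = lognormal_ci(freq.S, n_hat, var)
        return EstimateResult(
            n_hat=max(n_hat, freq.S),
            se=math.sqrt(max(var, 0.0)),
            ci_low=lo,
            ci_high=hi,
            method=self.method,
            diagnostics={"converged": converged, "iterations": iters,
                         "gamma_sq": _gamma_sq(n_hat, f, ps)},
        )


def sc1(freq: FrequencyData) -> EstimateResult:
    return SampleCoverage1(freq).fit()


def sc2(freq: FrequencyData) -> EstimateResult:
    return SampleCoverage2(freq).fit()


def ee_mh(data: CaptureData | FrequencyData) -> EstimateResult:
    return EstimatingEquationMh(data).fit()
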