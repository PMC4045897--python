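"""Full-likelihood closed-population models.

Two families:

* Finite-mixture heterogeneity models (Pledger-style): each animal belongs to
  one of G latent catchability classes with weights pi_g; the unconditional
  likelihood over (N, pi, p[, c]) is maximized directly, with optional
  additive-logit occasion (time) effects and a post-first-capture (behaviour)
  logit offset.  G = 1 without effects is the classical M0 likelihood.
* Huggins conditional likelihood with individual covariates: a logistic model
  for occasion-level capture probability fitted conditional on being caught
  at least once, with population size recovered by the Horvitz-Thompson sum
  N-hat = sum_i 1 / p*_i over the animals seen, p*_i being each animal's
  probability of at least one capture (evaluated at first-capture
  probabilities, i.e. without any behaviour effect).

Model selection in both families is by minimum AIC, ties going to the model
with fewer parameters.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .base import AbundanceModel, EstimateResult, lognormal_ci
from .data import CaptureData

__all__ = [
    "FiniteMixture",
    "HugginsHT",
    "finite_mixture_fit",
    "select_mixture_aic",
    "huggins_ht_fit",
    "select_huggins_aic",
]

_CHI2_95 = float(stats.chi2.ppf(0.95, df=1))


def _expit(x):
    return special.expit(x)


# -- finite mixture --------------------------------------------------------


@dataclass
class _MixtureSpec:
    G: int
    time_effects: bool
    behaviour: bool

    @property
    def label(self) -> str:
        tags = []
        if self.G > 1:
            tags.append(f"h{self.G}")
        if self.time_effects:
            tags.append("t")
        if self.behaviour:
            tags.append("b")
        return "M" + ("".join(tags) or "0")


class FiniteMixture(AbundanceModel):
    """Finite-mixture closed-population model fitted by full likelihood.

    Parameters are optimized on unconstrained scales (log for N - S, logit
    for probabilities, softmax for weights) from ``n_starts`` seeded random
    starting points, keeping the best.  ``fit`` returns an
    :class:`EstimateResult` whose diagnostics carry the mixture parameters,
    the log-likelihood, and AIC (counting N among the free parameters).
    """

    def __init__(self, data: CaptureData, G: int = 1, time_effects: bool = False,
                 behaviour: bool = False, n_starts: int = 5, seed: int = 0,
                 compute_ci: bool = True):
        if G not in (1, 2, 3):
            raise ValueError("G must be 1, 2 or 3")
        if data.n_occasions < 2:
            raise ValueError("need at least two occasions")
        self.data = data
        self.spec = _MixtureSpec(G, time_effects, behaviour)
        self.n_starts = n_starts
        self.seed = seed
        self.compute_ci = compute_ci
        self.method = "FiniteMixture[" + self.spec.label + "]"
        self._prepare()

    def _prepare(self) -> None:
        m = self.data.matrix.astype(np.int8)
        self.S = m.shape[0]
        self.t = m.shape[1]
        self.h = m
        self.counts = m.sum(axis=1)
        first = np.argmax(m == 1, axis=1)
        self.first = first
        # number of free parameters: N, pi (G-1), component intercepts,
        # time offsets (t-1), behaviour offset
        sp = self.spec
        self.k_params = 1 + (sp.G - 1) + sp.G
        if sp.time_effects:
            self.k_params += self.t - 1
        if sp.behaviour:
            self.k_params += 1

    # parameter vector: [eta, pi_logits (G-1), a_g (G), b_j (t-1 if time),
    #                    d (if behaviour)]
    def _unpack(self, theta: np.ndarray):
        sp = self.spec
        i = 1
        eta = theta[0]
        raw = np.concatenate([[0.0], theta[i:i + sp.G - 1]])
        i += sp.G - 1
        pi = np.exp(raw - raw.max())
        pi = pi / pi.sum()
        a = theta[i:i + sp.G]
        i += sp.G
        b = np.zeros(self.t)
        if sp.time_effects:
            b[1:] = theta[i:i + self.t - 1]
            i += self.t - 1
        d = theta[i] if sp.behaviour else 0.0
        return eta, pi, a, b, d

    def _loglik_terms(self, theta: np.ndarray) -> tuple[float, float]:
        """(log P(unseen), sum of log history probabilities)."""
        _, pi, a, b, d = self._unpack(theta)
        # logits per component x occasion
        logit_p = a[:, None] + b[None, :]          # (G, t) first-capture
        logp = -np.logaddexp(0.0, -logit_p)        # log expit
        logq = -np.logaddexp(0.0, logit_p)         # log(1 - expit)
        h = self.h
        if not self.spec.behaviour:
            # (S, G): sum_j h log p + (1-h) log q
            ll_ind = h @ logp.T + (1 - h) @ logq.T
        else:
            logit_c = logit_p + d
            logpc = -np.logaddexp(0.0, -logit_c)
            logqc = -np.logaddexp(0.0, logit_c)
            occ = np.arange(self.t)[None, :]
            pre = occ <= self.first[:, None]       # up to and incl. first capture
            hp = h * pre
            hq = (1 - h) * pre
            hcp = h * (~pre)
            hcq = (1 - h) * (~pre)
            ll_ind = (hp @ logp.T + hq @ logq.T + hcp @ logpc.T + hcq @ logqc.T)
        log_pi = np.log(pi)
        ll_seen = special.logsumexp(ll_ind + log_pi[None, :], axis=1).sum()
        log_p0 = float(special.logsumexp(logq.sum(axis=1) + log_pi))
        return log_p0, float(ll_seen)

    def loglik(self, theta: np.ndarray) -> float:
        eta = theta[0]
        N = self.S + math.exp(min(eta, 30.0))
        log_p0, ll_seen = self._loglik_terms(theta)
        return (
            float(special.gammaln(N + 1) - special.gammaln(N - self.S + 1))
            + (N - self.S) * log_p0
            + ll_seen
        )

    def _starts(self) -> list[np.ndarray]:
        rng = np.random.default_rng(self.seed)
        sp = self.spec
        p_bar = self.counts.mean() / self.t
        base_logit = special.logit(np.clip(p_bar, 0.02, 0.98))
        starts = []
        for s in range(max(self.n_starts, 1)):
            eta = math.log(max(0.3 * self.S, 1.0)) + rng.normal(0, 0.7)
            pil = rng.normal(0, 1, size=sp.G - 1)
            spread = 0.0 if (sp.G == 1 or s == 0) else rng.uniform(0.5, 2.5)
            a = base_logit + np.linspace(-spread, spread, sp.G) + rng.normal(0, 0.3, sp.G)
            theta = [eta, *pil, *a]
            if sp.time_effects:
                theta.extend(rng.normal(0, 0.2, self.t - 1))
            if sp.behaviour:
                theta.append(rng.normal(0, 0.5))
            starts.append(np.array(theta))
        return starts

    def _optimize(self, theta0: np.ndarray):
        return optimize.minimize(
            lambda th: -self.loglik(th), theta0, method="L-BFGS-B",
            options={"maxiter": 500},
        )

    def fit(self) -> EstimateResult:
        best = None
        any_ok = False
        for theta0 in self._starts():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = self._optimize(theta0)
            if not np.isfinite(res.fun):
                continue
            any_ok = any_ok or res.success
            if best is None or res.fun < best.fun:
                best = res
        if best is None:
            raise RuntimeError("all mixture starts failed")
        theta = best.x
        eta, pi, a, b, d = self._unpack(theta)
        N_hat = self.S + math.exp(min(eta, 30.0))
        ll = self.loglik(theta)
        aic = -2 * ll + 2 * self.k_params
        order = np.argsort(a)
        p_comp = _expit(a[order])
        diag = {
            "G": self.spec.G,
            "pi": pi[order].tolist(),
            "p": p_comp.tolist(),
            "loglik": ll,
            "aic": aic,
            "converged": bool(any_ok),
            "model": self.spec.label,
        }
        if self.spec.time_effects:
            diag["time_logit_offsets"] = b[1:].tolist()
        if self.spec.behaviour:
            diag["c"] = _expit(a[order] + d).tolist()

        if not self.compute_ci:
            return EstimateResult(
                n_hat=N_hat, se=float("nan"), ci_low=float("nan"),
                ci_high=float("nan"), method=self.method, diagnostics=diag,
            )
        lo, hi, se = self._profile_ci(theta, ll, N_hat)
        return EstimateResult(
            n_hat=N_hat, se=se, ci_low=min(lo, N_hat), ci_high=max(hi, N_hat),
            method=self.method, diagnostics=diag,
        )

    def _profile_loglik(self, N: float, theta_init: np.ndarray) -> float:
        def negll(rest: np.ndarray) -> float:
            th = np.concatenate([[math.log(max(N - self.S, 1e-9))], rest])
            log_p0, ll_seen = self._loglik_terms(th)
            ll = (
                float(special.gammaln(N + 1) - special.gammaln(N - self.S + 1))
                + (N - self.S) * log_p0
                + ll_seen
            )
            return -ll

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(negll, theta_init[1:], method="L-BFGS-B",
                                    options={"maxiter": 200})
        return -float(res.fun)

    def _profile_ci(self, theta: np.ndarray, ll_max: float,
                    N_hat: float) -> tuple[float, float, float]:
        cut = ll_max - _CHI2_95 / 2

        def g(N: float) -> float:
            return self._profile_loglik(N, theta) - cut

        span = max(N_hat - self.S, 2.0)
        lo_bracket = N_hat
        step = span
        lo = float(self.S)
        while lo_bracket > self.S + 1e-6:
            cand = max(self.S + 1e-6, lo_bracket - step)
            if g(cand) < 0:
                lo = float(optimize.brentq(g, cand, lo_bracket, xtol=1e-3))
                break
            lo_bracket = cand
            step *= 2
        hi_bracket = N_hat + span
        while g(hi_bracket) >= 0 and hi_bracket < 50 * max(N_hat, 10):
            hi_bracket += span
            span *= 2
        hi = (
            float(optimize.brentq(g, N_hat, hi_bracket, xtol=1e-3))
            if g(hi_bracket) < 0
            else float("inf")
        )
        se = (hi - lo) / (2 * 1.959964) if np.isfinite(hi) else float("nan")
        return lo, hi, se


def finite_mixture_fit(data: CaptureData, G: int = 1, time_effects: bool = False,
                       behaviour: bool = False, n_starts: int = 5, seed: int = 0,
                       compute_ci: bool = True) -> EstimateResult:
    return FiniteMixture(data, G=G, time_effects=time_effects,
                         behaviour=behaviour, n_starts=n_starts, seed=seed,
                         compute_ci=compute_ci).fit()


def select_mixture_aic(data: CaptureData, candidates=None, n_starts: int = 5,
                       seed: int = 0) -> EstimateResult:
    """Fit each (G, time, behaviour) candidate and return the minimum-AIC fit.

    Default candidate set: {pi(.)p(.), pi(.)p(t), pi(.)p(.)c(.)} x G in {1, 2}.
    Ties in AIC go to the model with fewer parameters.
    """
    if candidates is None:
        candidates = [
            (1, False, False), (1, True, False), (1, False, True),
            (2, False, False), (2, True, False), (2, False, True),
        ]
    if not candidates:
        raise ValueError("need at least one candidate model")
    fits = []
    failures = []
    for G, te, be in candidates:
        try:
            model = FiniteMixture(data, G=G, time_effects=te, behaviour=be,
                                  n_starts=n_starts, seed=seed, compute_ci=False)
            fits.append((model, model.fit()))
        except (RuntimeError, ValueError) as exc:
            failures.append(((G, te, be), str(exc)))
    if not fits:
        raise RuntimeError(f"all candidate models failed: {failures}")
    fits.sort(key=lambda mr: (round(mr[1].diagnostics["aic"], 9),
                              mr[0].k_params, mr[0].method))
    best_model, _ = fits[0]
    result = FiniteMixture(
        data, G=best_model.spec.G, time_effects=best_model.spec.time_effects,
        behaviour=best_model.spec.behaviour, n_starts=n_starts, seed=seed,
    ).fit()
    result.diagnostics["aic_table"] = pd.DataFrame(
        [
            {"model": m.spec.label, "G": m.spec.G, "k": m.k_params,
             "aic": r.diagnostics["aic"], "loglik": r.diagnostics["loglik"]}
            for m, r in fits
        ]
    )
    return result


# -- Huggins conditional likelihood + Horvitz-Thompson ---------------------


def _parse_formula(formula: str) -> list[str]:
    rhs = formula.split("~", 1)[1] if "~" in formula else formula
    terms = [t.strip() for t in rhs.split("+")]
    return [t for t in terms if t and t != "1"]


class HugginsHT(AbundanceModel):
    """Logistic capture model fitted conditionally on capture >= once.

    *formula* names the occasion-level design: ``time`` (occasion factors),
    ``behaviour`` (previously-captured indicator), and any categorical
    individual covariate column present in ``data.covariates`` (e.g. ``age``,
    ``hut``).  Abundance is the Horvitz-Thompson sum over captured animals.
    """

    def __init__(self, data: CaptureData, formula: str = "~ 1"):
        if data.n_occasions < 2:
            raise ValueError("need at least two occasions")
        self.data = data
        self.terms = _parse_formula(formula)
        self.method = "Huggins[~" + (" + ".join(self.terms) or " 1") + "]"
        self._build_design()

    def _build_design(self) -> None:
        data = self.data
        S, t = data.n_individuals, data.n_occasions
        cols: list[np.ndarray] = [np.ones((S, t))]
        names = ["intercept"]
        self._behaviour_col: int | None = None
        for term in self.terms:
            if term == "time":
                for j in range(1, t):
                    col = np.zeros((S, t))
                    col[:, j] = 1.0
                    cols.append(col)
                    names.append(f"occ[{data.occasions[j]}]")
            elif term == "behaviour":
                m = data.matrix
                prior = np.zeros((S, t))
                prior[:, 1:] = np.cumsum(m[:, :-1], axis=1) > 0
                cols.append(prior)
                names.append("behaviour")
                self._behaviour_col = len(names) - 1
            else:
                if data.covariates is None or term not in data.covariates.columns:
                    raise ValueError(f"missing covariate {term!r}")
                vals = data.covariates.loc[data.individuals, term]
                if vals.isna().any():
                    missing = vals[vals.isna()].index.tolist()
                    raise ValueError(f"missing {term!r} for individuals {missing}")
                levels = sorted(map(str, vals.unique()))
                for level in levels[1:]:
                    ind = (vals.astype(str) == level).to_numpy(dtype=float)
                    cols.append(np.repeat(ind[:, None], t, axis=1))
                    names.append(f"{term}[{level}]")
        self.X = np.stack(cols, axis=2)  # (S, t, K)
        self.names = names

    def _logit_p(self, beta: np.ndarray, first_capture: bool = False) -> np.ndarray:
        X = self.X
        if first_capture and self._behaviour_col is not None:
            X = X.copy()
            X[:, :, self._behaviour_col] = 0.0
        return X @ beta

    def _cond_negll(self, beta: np.ndarray) -> float:
        y = self.data.matrix
        lp = self._logit_p(beta)
        log_p = -np.logaddexp(0.0, -lp)
        log_q = -np.logaddexp(0.0, lp)
        ll = (y * log_p + (1 - y) * log_q).sum()
        lq_first = -np.logaddexp(0.0, self._logit_p(beta, first_capture=True))
        log_miss = lq_first.sum(axis=1)  # log prod (1 - p~_ij)
        log_pstar = np.log1p(-np.exp(np.minimum(log_miss, -1e-12)))
        return -(ll - log_pstar.sum())

    def fit(self) -> EstimateResult:
        K = self.X.shape[2]
        beta0 = np.zeros(K)
        p_bar = self.data.matrix.mean()
        beta0[0] = special.logit(np.clip(p_bar, 0.02, 0.98))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(self._cond_negll, beta0, method="BFGS",
                                    options={"maxiter": 500})
        beta = res.x
        separation = bool(np.abs(beta).max() > 15)
        lq_first = -np.logaddexp(0.0, self._logit_p(beta, first_capture=True))
        p_star = -np.expm1(lq_first.sum(axis=1))
        p_star = np.clip(p_star, 1e-12, 1.0)
        N_hat = float((1 / p_star).sum())
        ll = -float(res.fun)
        aic = 2 * res.fun + 2 * K

        # HT variance + delta-method term for beta uncertainty
        var_ht = float(((1 - p_star) / p_star**2).sum())
        try:
            cov_beta = res.hess_inv if isinstance(res.hess_inv, np.ndarray) else res.hess_inv.todense()
            grad = np.zeros(K)
            for k in range(K):
                h = 1e-5 * max(1.0, abs(beta[k]))
                bp, bm = beta.copy(), beta.copy()
                bp[k] += h
                bm[k] -= h
                grad[k] = (self._ht_of(bp) - self._ht_of(bm)) / (2 * h)
            var_beta = float(grad @ cov_beta @ grad)
        except Exception:  # pragma: no cover - numerical fallback
            var_beta = 0.0
        var = var_ht + max(var_beta, 0.0)
        se = math.sqrt(var)
        lo, hi = lognormal_ci(self.data.n_individuals, N_hat, var)
        return EstimateResult(
            n_hat=N_hat, se=se, ci_low=min(lo, N_hat), ci_high=max(hi, N_hat),
            method=self.method,
            diagnostics={
                "beta": dict(zip(self.names, beta.tolist())),
                "loglik": ll,
                "aic": float(aic),
                "k": K,
                "separation": separation,
                "converged": bool(res.success),
                "p_star_min": float(p_star.min()),
            },
        )

    def _ht_of(self, beta: np.ndarray) -> float:
        lq = -np.logaddexp(0.0, self._logit_p(beta, first_capture=True))
        p_star = np.clip(-np.expm1(lq.sum(axis=1)), 1e-12, 1.0)
        return float((1 / p_star).sum())


def huggins_ht_fit(data: CaptureData, formula: str = "~ 1") -> EstimateResult:
    return HugginsHT(data, formula).fit()


def select_huggins_aic(data: CaptureData, candidates: dict[str, str] | None = None
                       ) -> EstimateResult:
    """Minimum-AIC Huggins model among {M0, Mt, Mh(cov), Mth(cov)}-style fits."""
    if candidates is None:
        covs = []
        if data.covariates is not None:
            covs = [c for c in ("age", "hut", "site") if c in data.covariates.columns]
        cov_rhs = " + ".join(covs)
        candidates = {"M0": "~ 1", "Mt": "~ time"}
        if cov_rhs:
            candidates["Mh(cov)"] = "~ " + cov_rhs
            candidates["Mth(cov)"] = "~ time + " + cov_rhs
    if not candidates:
        raise ValueError("need at least one candidate model")
    fits = []
    failures = []
    for label, formula in candidates.items():
        try:
            model = HugginsHT(data, formula)
            fits.append((label, model, model.fit()))
        except (RuntimeError, ValueError) as exc:
            failures.append((label, str(exc)))
    if not fits:
        raise RuntimeError(f"all candidate models failed: {failures}")
    fits.sort(key=lambda lmr: (round(lmr[2].diagnostics["aic"], 9),
                               lmr[2].diagnostics["k"], lmr[0]))
    label, _, best = fits[0]
    best.diagnostics["selected"] = label
    best.diagnostics["aic_table"] = pd.DataFrame(
        [{"model": lbl, "k": r.diagnostics["k"], "aic": r.diagnostics["aic"],
          "loglik": r.diagnostics["loglik"]} for lbl, _, r in fits]
    )
    return best
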