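"""Reference-population construction and estimator performance evaluation.

When no census is possible, an intensively sampled closed population can
stand in for truth: for every primary period except the last, the reference
population collects all animals known (from captures in that or any later
period) to have been present.  Two variants:

* ``partly`` independent — animals caught only in the focal period still
  contribute (the same capture enters both the reference count and the
  estimation data);
* ``fully`` independent — those period-only animals are dropped from both
  the reference and the estimation data, so no capture is used twice.

Juveniles born in later periods are excluded in both modes (they were not
yet part of the population).  The inclusion threshold

    p_tr = 1 - 0.05^(1/n)

is the daily capture probability at which an animal is detected at least
once in n occasions with probability 0.95; animals below it may be missing
from the reference.

Performance of an estimator across periods is summarized by relative bias,
relative precision and relative accuracy of the ratios r_i = N-hat_i / N_ref_i:

    bias      = mean(r_i - 1)
    precision = mean((r_i - rbar)^2)
    accuracy  = mean((r_i - 1)^2)  =  precision + bias^2,

plus the count of periods whose 95% CI covers the reference and the mean CI
width.  Estimators are ranked per criterion by |value| (CI width by value),
ties broken by label; methods within 50% of the best are flagged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .base import EstimateResult
from .data import CaptureData, restrict_to_period

__all__ = [
    "ReferencePopulation",
    "EstimatorPerformance",
    "build_reference",
    "p_threshold",
    "performance_metrics",
    "ci_coverage_and_width",
    "rank_estimators",
]


@dataclass
class ReferencePopulation:
    """Known-alive animal set standing in for true N in one primary period."""

    period: str
    members: frozenset[str]
    n_occ: int
    p_tr: float
    mode: str

    @property
    def N_ref(self) -> int:
        return len(self.members)


def p_threshold(n_occ: int) -> float:
    """Daily capture probability giving >= 95% detection over n_occ occasions."""
    if n_occ < 1:
        raise ValueError("need at least one occasion")
    return 1 - 0.05 ** (1 / n_occ)


def _period_index(data: CaptureData, period: str) -> int:
    periods = data.primary_periods
    if period not in periods:
        raise ValueError(f"unknown primary period {period!r}")
    return periods.index(period)


def build_reference(full: CaptureData, period: str, mode: str = "partly"
                    ) -> tuple[ReferencePopulation, CaptureData]:
    """Reference population for *period* plus the matching estimation data.

    ``partly``: members are animals captured in this or any later period,
    minus juveniles born after it; estimation data is the plain restriction
    to the period.  ``fully``: animals captured in this period but never
    after it are additionally removed — from the reference and from the
    estimation data.
    """
    if mode not in ("partly", "fully"):
        raise ValueError(f"mode must be 'partly' or 'fully', got {mode!r}")
    period = str(period)
    idx = _period_index(full, period)
    periods = full.primary_periods
    if idx == len(periods) - 1:
        raise ValueError(
            f"{period!r} is the last primary period: no reference constructible"
        )
    focal_occ = full.occasions_of(period)
    later_occ = [o for p in periods[idx + 1:] for o in full.occasions_of(p)]
    in_focal = full.distinct_in(focal_occ)
    in_later = full.distinct_in(later_occ)
    members = in_focal | in_later
    # juveniles born in later primary periods were not yet present
    order = {p: i for i, p in enumerate(periods)}
    unborn = {
        i for i in members
        if full.birth_period.get(i) is not None
        and order.get(full.birth_period[i], -1) > idx
    }
    members -= unborn
    est = restrict_to_period(full, period)
    if mode == "partly":
        n_occ = len(focal_occ) + len(later_occ)
    else:
        period_only = (in_focal - in_later) & members
        members -= period_only
        keep = [i for i in est.individuals if i not in period_only]
        if not keep:
            raise ValueError(
                f"no estimation data left for {period!r} in fully mode"
            )
        sel = np.array([i in set(keep) for i in est.individuals])
        est = CaptureData(
            individuals=keep,
            occasions=est.occasions,
            matrix=est.matrix[sel],
            primary_of=est.primary_of,
            covariates=(est.covariates.loc[keep]
                        if est.covariates is not None else None),
            birth_period={i: p for i, p in est.birth_period.items() if i in set(keep)},
        )
        n_occ = len(later_occ)
    ref = ReferencePopulation(
        period=period,
        members=frozenset(members),
        n_occ=n_occ,
        p_tr=p_threshold(n_occ),
        mode=mode,
    )
    return ref, est


# -- performance metrics ---------------------------------------------------


@dataclass
class EstimatorPerformance:
    """Bias / precision / accuracy of one estimator across reference periods."""

    rel_bias: float
    rel_precision: float
    rel_accuracy: float
    coverage_count: int | None = None
    mean_ci_width: float | None = None
    n_periods: int = 0
    label: str = ""
    ratios: list[float] = field(default_factory=list)


def _point(e) -> float:
    return e.n_hat if isinstance(e, EstimateResult) else float(e)


def _ref_size(r) -> float:
    return float(r.N_ref) if isinstance(r, ReferencePopulation) else float(r)


def performance_metrics(estimates, refs, label: str = "") -> EstimatorPerformance:
    """Relative bias, precision and accuracy of estimates against references.

    Accepts :class:`EstimateResult` objects or plain numbers for the
    estimates, and :class:`ReferencePopulation` objects or plain sizes for
    the references.  Uses the 1/n (population) convention throughout, so
    accuracy = precision + bias^2 exactly.
    """
    if len(estimates) != len(refs):
        raise ValueError(
            f"{len(estimates)} estimates but {len(refs)} references"
        )
    if len(estimates) < 1:
        raise ValueError("need at least one period")
    r = np.array([_point(e) / _ref_size(nr) for e, nr in zip(estimates, refs)])
    bias = float(np.mean(r - 1))
    precision = float(np.mean((r - r.mean()) ** 2))
    accuracy = float(np.mean((r - 1) ** 2))
    perf = EstimatorPerformance(
        rel_bias=bias,
        rel_precision=precision,
        rel_accuracy=accuracy,
        n_periods=len(r),
        label=label,
        ratios=r.tolist(),
    )
    if all(isinstance(e, EstimateResult) for e in estimates):
        cov, width = ci_coverage_and_width(estimates, refs)
        perf.coverage_count = cov
        perf.mean_ci_width = width
    return perf


def ci_coverage_and_width(estimates, refs) -> tuple[int, float]:
    """Count of references inside the 95% CIs (strict bounds) and mean CI span.

    Periods with a missing/non-finite CI are skipped with a warning.
    """
    if len(estimates) != len(refs):
        raise ValueError("length mismatch between estimates and references")
    count = 0
    widths = []
    skipped = 0
    for e, nr in zip(estimates, refs):
        lo, hi = e.ci_low, e.ci_high
        if not (np.isfinite(lo) and np.isfinite(hi)):
            skipped += 1
            continue
        nref = _ref_size(nr)
        if lo <= nref <= hi:
            count += 1
        widths.append(hi - lo)
    if skipped:
        warnings.warn(f"{skipped} period(s) without a finite CI skipped",
                      stacklevel=2)
    return count, float(np.mean(widths)) if widths else float("nan")


_CRITERIA = {
    "rel_bias": True,       # rank by |value|
    "rel_precision": True,
    "rel_accuracy": True,
    "mean_ci_width": False,  # rank by value
}


def rank_estimators(summaries: dict[str, EstimatorPerformance]) -> pd.DataFrame:
    """Rank estimators per criterion (1 = best, closest to zero).

    Returns a DataFrame indexed by estimator label with, per criterion, the
    value, the rank, and a ``*_top`` flag marking estimators within 50% of
    the best (|value| < 1.5 x best).  Ties share a rank; label order breaks
    presentation ties.
    """
    if len(summaries) < 2:
        raise ValueError("ranking needs at least two estimators")
    labels = sorted(summaries)
    out = pd.DataFrame(index=pd.Index(labels, name="estimator"))
    for crit, use_abs in _CRITERIA.items():
        vals = {}
        for lbl in labels:
            v = getattr(summaries[lbl], crit)
            if v is None:
                v = np.nan
            vals[lbl] = abs(v) if use_abs else v
        series = pd.Series(vals)
        out[crit] = [getattr(summaries[lbl], crit) for lbl in labels]
        out[crit + "_rank"] = series.rank(method="min").astype("Int64")
        best = series.min()
        out[crit + "_top"] = series < 1.5 * best + 1e-15
    return out
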