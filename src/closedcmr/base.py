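"""Shared model/results machinery for the abundance estimators.

Every estimator in this package is a small model object constructed from data
whose :meth:`~AbundanceModel.fit` returns an :class:`EstimateResult` carrying
the point estimate, its standard error, a 95% confidence interval and
method-specific diagnostics.  Module-level convenience functions (e.g.
``chao_moment(freq)``) simply construct the model and fit it.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass, field

import numpy as np

Z95 = 1.959963984540054  # two-sided 95% normal quantile

__all__ = ["EstimateResult", "AbundanceModel", "Z95", "lognormal_ci"]


@dataclass
class EstimateResult:
    """Point estimate of population size with uncertainty and diagnostics.

    ``n_hat`` is kept real-valued; rounding (half away from zero) happens only
    at report time.  ``diagnostics`` carries method-specific values such as
    per-split estimates, coverage and CV, the selected model, or AIC tables.
    """

    n_hat: float
    se: float
    ci_low: float
    ci_high: float
    method: str
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = (self.ci_low, self.n_hat, self.ci_high)
        if all(np.isfinite(vals)) and not (
            self.ci_low <= self.n_hat + 1e-9 and self.n_hat <= self.ci_high + 1e-9
        ):
            raise ValueError(
                f"confidence interval ({self.ci_low}, {self.ci_high}) does not "
                f"bracket the estimate {self.n_hat}"
            )

    @property
    def n_hat_rounded(self) -> int:
        """Point estimate rounded half away from zero."""
        return int(np.floor(self.n_hat + 0.5))

    def summary(self) -> str:
        lines = [
            f"Population size estimate [{self.method}]",
            "-" * 44,
            f"  N-hat     {self.n_hat:12.2f}",
            f"  SE        {self.se:12.2f}",
            f"  95% CI    ({self.ci_low:.2f}, {self.ci_high:.2f})",
        ]
        for key, val in self.diagnostics.items():
            if isinstance(val, (int, float, np.floating, np.integer)):
                lines.append(f"  {key:<10}{float(val):12.4f}")
        return "\n".join(lines)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.summary()


class AbundanceModel(ABC):
    """Base class: construct from data, ``fit()`` to an :class:`EstimateResult`."""

    method: str = "abstract"

    @abstractmethod
    def fit(self) -> EstimateResult: ...


def lognormal_ci(S: float, n_hat: float, var: float, z: float = Z95) -> tuple[float, float]:
    """Log-normal 95% interval on the unseen count f0 = N-hat - S.

    The standard closed-population interval: the lower bound can never fall
    below the number of animals actually seen.
    """
    f0 = n_hat - S
    if f0 <= 0 or var <= 0:
        half = z * np.sqrt(max(var, 0.0))
        lo = min(max(S, n_hat - half), n_hat)
        return lo, max(n_hat + half, S)
    sigma2 = np.log1p(var / f0**2)
    C = np.exp(z * np.sqrt(sigma2))
    return S + f0 / C, S + f0 * C
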