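"""Bundled example data: a two-year capture-mark-recapture field study of the
arboreal gecko *Gehyra variegata* sampled bimonthly under a robust design.

Two published summary tables are transcribed as CSV:

* per-period capture-frequency tables (f_1..f_8, S), with the reference
  population size (animals known alive from that period onward), the number
  of later-study occasions used to build it, the inclusion threshold p_tr,
  and the estimated CV of individual catchability — in the ``partly`` and
  ``fully`` independent reference constructions;
* the abundance estimates (with 95% CIs) produced by the original analysis
  programs (CAPTURE/MARK, CARE-2, and Lincoln-Petersen variants) on the same
  data, useful for benchmarking and as evaluation inputs.

The number of pooled estimation occasions per period was not published
(frequencies run to f_8, so at most 8); the frequency tables therefore carry
``t`` as unknown, and estimators that need the occasion count or per-occasion
sample sizes refuse them explicitly.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from ..data import FrequencyData

__all__ = ["load_gecko_frequencies", "load_gecko_reported", "gecko_metadata"]


def _read(name: str) -> pd.DataFrame:
    with resources.files(__package__).joinpath(name).open() as fh:
        return pd.read_csv(fh)


def gecko_metadata(mode: str = "partly") -> pd.DataFrame:
    """Per-period metadata: reference size, occasions used, p_tr, CV."""
    if mode not in ("partly", "fully"):
        raise ValueError("mode must be 'partly' or 'fully'")
    return _read(f"gecko_{mode}_frequencies.csv").set_index("period")


def load_gecko_frequencies(mode: str = "partly") -> dict[str, FrequencyData]:
    """Capture-frequency data per primary period (occasion count unknown)."""
    meta = gecko_metadata(mode)
    out: dict[str, FrequencyData] = {}
    for period, row in meta.iterrows():
        f = [int(row[f"f{k}"]) for k in range(1, 9)]
        out[str(period)] = FrequencyData(f=f, t=None, n_j=None)
    return out


def load_gecko_reported(mode: str = "partly") -> pd.DataFrame:
    """Estimates and 95% CIs from the original analysis, per estimator/period."""
    if mode not in ("partly", "fully"):
        raise ValueError("mode must be 'partly' or 'fully'")
    return _read(f"gecko_{mode}_reported.csv")
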