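"""Benchmark orchestration and report rendering.

``run_benchmark`` drives the whole evaluation: for every primary period
except the last it builds the requested reference population(s), runs each
registered estimator on that period's (possibly adjusted) capture data, and
assembles an estimates table (one row per estimator, one column per period,
cells formatted as ``N-hat (low-high)``) plus a rank table over the four
performance criteria.  Estimators that cannot run on the given input (for
instance occasion-level methods on a frequency-only table) are recorded as
``not applicable`` rather than crashing; hard numeric failures abort.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
import yaml

from .base import EstimateResult
from .coverage import ee_mh, sc1, sc2
from .data import CaptureData, FrequencyData, capture_frequencies, read_capture_data
from .frequency import chao_moment, jackknife_interpolated, trunc_geom_fit
from .likelihood import select_huggins_aic, select_mixture_aic
from .petersen import lp, mlp, mpe
from .reference import (
    EstimatorPerformance,
    build_reference,
    performance_metrics,
    rank_estimators,
)
from .simulate import SimulationConfig, simulate_robust_design

log = logging.getLogger("closedcmr")

__all__ = ["BenchmarkConfig", "run_benchmark", "benchmark_frequency_tables",
           "render_tables", "ESTIMATORS", "format_estimate"]


class NotApplicable(Exception):
    """Estimator cannot run on this input (wrong data granularity)."""


def _freq_only(fn: Callable[[FrequencyData], EstimateResult]):
    def run(data) -> EstimateResult:
        freq = capture_frequencies(data) if isinstance(data, CaptureData) else data
        try:
            return fn(freq)
        except ValueError as exc:
            raise NotApplicable(str(exc)) from exc
    return run


def _capture_only(fn: Callable[[CaptureData], EstimateResult]):
    def run(data) -> EstimateResult:
        if not isinstance(data, CaptureData):
            raise NotApplicable("needs occasion-level capture histories")
        return fn(data)
    return run


# name -> (runner, report decimals)
ESTIMATORS: dict[str, tuple[Callable, int]] = {
    "LP": (_capture_only(lp), 2),
    "MLP": (_capture_only(mlp), 2),
    "MPE": (_capture_only(mpe), 2),
    "ME": (_freq_only(chao_moment), 0),
    "IntJK": (_freq_only(jackknife_interpolated), 0),
    "TruncGeom": (_freq_only(trunc_geom_fit), 0),
    "SC1": (_freq_only(sc1), 2),
    "SC2": (_freq_only(sc2), 2),
    "EE": (_capture_only(ee_mh), 2),
    "FiniteMixtures": (_capture_only(select_mixture_aic), 2),
    "GSRUN": (_capture_only(select_huggins_aic), 2),
}


@dataclass
class BenchmarkConfig:
    """What to run: input data (files or simulation), estimators, modes."""

    estimators: list[str] = dataclass_field(
        default_factory=lambda: ["LP", "MLP", "MPE", "ME", "IntJK", "TruncGeom",
                                 "SC1", "SC2", "EE"]
    )
    reference_modes: list[str] = dataclass_field(default_factory=lambda: ["partly"])
    input_csv: str | None = None
    input_design: str | None = None
    simulation: SimulationConfig | None = None
    fixture: str | None = None  # "gecko": packaged frequency tables
    output_dir: str = "benchmark_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.estimators:
            raise ValueError("need at least one estimator")
        unknown = [e for e in self.estimators if e not in ESTIMATORS]
        if unknown:
            raise ValueError(f"unknown estimators: {unknown} "
                             f"(registered: {sorted(ESTIMATORS)})")

    @classmethod
    def from_yaml(cls, path) -> "BenchmarkConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**{k: v for k, v in raw.items()})
        if sim is not None:
            if "heterogeneity" in sim and isinstance(sim["heterogeneity"], list):
                sim["heterogeneity"] = tuple(sim["heterogeneity"])
            cfg.simulation = SimulationConfig(**sim)
        return cfg


def format_estimate(n_hat: float, ci_low: float, ci_high: float,
                    decimals: int = 2) -> str:
    """Render ``N-hat (low-high)``; integer rounding is half away from zero."""
    def fmt(x: float) -> str:
        if not np.isfinite(x):
            return ""
        if decimals == 0:
            return str(int(np.floor(x + 0.5)))
        return f"{x:.{decimals}f}"
    if not (np.isfinite(ci_low) and np.isfinite(ci_high)):
        return f"{fmt(n_hat)} (–)"
    return f"{fmt(n_hat)} ({fmt(ci_low)}–{fmt(ci_high)})"


def _load_input(config: BenchmarkConfig) -> CaptureData:
    if config.simulation is not None:
        sim = SimulationConfig(**{**config.simulation.__dict__,
                                  "seed": config.simulation.seed or config.seed})
        data, _ = simulate_robust_design(sim)
        return data
    if config.input_csv is None:
        raise ValueError("config needs either input_csv or simulation")
    return read_capture_data(config.input_csv, format="csv",
                             design=config.input_design)


def benchmark_frequency_tables(freqs: dict[str, FrequencyData],
                               refs: dict[str, float] | None,
                               estimators: list[str]) -> dict[str, pd.DataFrame]:
    """Benchmark frequency-only inputs (e.g. published tables) per period.

    Estimators needing occasion-level data are reported ``not applicable``.
    Metrics and ranks are computed only for estimators applicable in every
    period, against the supplied reference sizes.
    """
    results: dict[str, dict[str, EstimateResult | None]] = {}
    for name in estimators:
        runner, _ = ESTIMATORS[name]
        results[name] = {}
        for period, freq in freqs.items():
            try:
                results[name][period] = runner(freq)
            except NotApplicable as exc:
                log.warning("%s not applicable in %s: %s", name, period, exc)
                results[name][period] = None
    est_rows = {
        name: {
            period: (
                format_estimate(r.n_hat, r.ci_low, r.ci_high, ESTIMATORS[name][1])
                if r is not None else "not applicable"
            )
            for period, r in results[name].items()
        }
        for name in estimators
    }
    est_table = pd.DataFrame.from_dict(est_rows, orient="index")
    est_table.index.name = "estimator"
    tables = {"estimates": est_table}
    if refs:
        summaries = {}
        for name in estimators:
            series = [results[name][p] for p in freqs]
            if any(r is None for r in series):
                continue
            summaries[name] = performance_metrics(
                series, [refs[p] for p in freqs], label=name
            )
        if summaries:
            tables["metrics"] = pd.DataFrame(
                {
                    n: {"rel_bias": s.rel_bias, "rel_precision": s.rel_precision,
                        "rel_accuracy": s.rel_accuracy,
                        "coverage_count": s.coverage_count,
                        "mean_ci_width": s.mean_ci_width}
                    for n, s in summaries.items()
                }
            ).T
        if len(summaries) >= 2:
            tables["ranks"] = rank_estimators(summaries)
    return tables


def run_benchmark(config: BenchmarkConfig, data: CaptureData | None = None
                  ) -> dict[str, pd.DataFrame]:
    """Run every estimator per period/mode; write and return the report tables.

    Returns (and writes to ``config.output_dir``) one estimates table and one
    rank table per reference mode, plus a coverage/metrics table.
    """
    outdir_fix = Path(config.output_dir)
    if data is None and config.fixture is not None:
        from .datasets import gecko_metadata, load_gecko_frequencies

        tables: dict[str, pd.DataFrame] = {}
        for mode in config.reference_modes:
            freqs = load_gecko_frequencies(mode)
            refs = gecko_metadata(mode)["N_ref"].to_dict()
            sub = benchmark_frequency_tables(freqs, refs, config.estimators)
            tables.update({f"{k}_{mode}": v for k, v in sub.items()})
        outdir_fix.mkdir(parents=True, exist_ok=True)
        for name, table in tables.items():
            table.to_csv(outdir_fix / f"{name}.csv")
            (outdir_fix / f"{name}.md").write_text(table.to_markdown())
        return tables
    if data is None:
        data = _load_input(config)
    periods = data.primary_periods
    if len(periods) < 2:
        raise ValueError("benchmark needs at least two primary periods")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}

    for mode in config.reference_modes:
        refs = []
        results: dict[str, dict[str, EstimateResult | None]] = {
            name: {} for name in config.estimators
        }
        for period in periods[:-1]:
            ref, est_data = build_reference(data, period, mode=mode)
            refs.append(ref)
            log.info("period %s (%s): N_ref=%d from %d occasions, p_tr=%.3f",
                     period, mode, ref.N_ref, ref.n_occ, ref.p_tr)
            for name in config.estimators:
                runner, _ = ESTIMATORS[name]
                try:
                    res = runner(est_data)
                except NotApplicable as exc:
                    log.warning("%s not applicable in %s: %s", name, period, exc)
                    res = None
                if res is not None and "aic_table" in res.diagnostics:
                    log.info("%s %s AIC table:\n%s", name, period,
                             res.diagnostics["aic_table"])
                if res is not None and "order" in res.diagnostics:
                    log.info("%s %s jackknife order %s", name, period,
                             res.diagnostics["order"])
                results[name][period] = res

        est_rows = {}
        for name in config.estimators:
            _, decimals = ESTIMATORS[name]
            est_rows[name] = {
                period: (
                    format_estimate(r.n_hat, r.ci_low, r.ci_high, decimals)
                    if r is not None else "not applicable"
                )
                for period, r in results[name].items()
            }
        est_table = pd.DataFrame.from_dict(est_rows, orient="index")
        est_table.index.name = "estimator"

        summaries: dict[str, EstimatorPerformance] = {}
        for name in config.estimators:
            series = [results[name][p] for p in periods[:-1]]
            if any(r is None for r in series):
                continue
            summaries[name] = performance_metrics(series, refs, label=name)
        metrics_table = pd.DataFrame(
            {
                name: {
                    "rel_bias": s.rel_bias,
                    "rel_precision": s.rel_precision,
                    "rel_accuracy": s.rel_accuracy,
                    "coverage_count": s.coverage_count,
                    "mean_ci_width": s.mean_ci_width,
                }
                for name, s in summaries.items()
            }
        ).T
        metrics_table.index.name = "estimator"
        tables[f"estimates_{mode}"] = est_table
        tables[f"metrics_{mode}"] = metrics_table
        if len(summaries) >= 2:
            tables[f"ranks_{mode}"] = rank_estimators(summaries)

    for name, table in tables.items():
        table.to_csv(outdir / f"{name}.csv")
        (outdir / f"{name}.md").write_text(table.to_markdown())
    return tables


def render_tables(results: dict[str, pd.DataFrame]) -> str:
    """All report tables as one Markdown document."""
    if not results:
        raise ValueError("no results to render")
    parts = []
    for name, table in results.items():
        parts.append(f"## {name}\n\n{table.to_markdown()}\n")
    return "\n".join(parts)


def main_logging() -> None:
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(levelname)s %(message)s")
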