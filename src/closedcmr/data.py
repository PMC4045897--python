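"""Capture-history containers and I/O for closed-population mark-recapture.

The central object is :class:`CaptureData`, a binary individual-by-occasion
detection matrix with an optional robust-design structure: occasions are
grouped into primary periods (population open between periods, closed within
them), and individuals may carry covariates (age class per period, site) and
a birth period used by the reference-population rules.

:class:`FrequencyData` is the reduction to capture frequencies f_k (number of
individuals caught exactly k times); most heterogeneity estimators consume
only this summary.

Two interchange formats are supported: a CSV matrix (header of occasion
labels, first column the individual identifier) with an optional YAML sidecar
for the design, and the MARK ``.inp`` encounter-history format (fixed-width
0/1 histories followed by a frequency and ``;``, ``/* */`` comments ignored).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CaptureData",
    "FrequencyData",
    "CaptureFormatError",
    "read_capture_data",
    "write_capture_data",
    "pool_occasions",
    "capture_frequencies",
    "restrict_to_period",
]


class CaptureFormatError(ValueError):
    """Malformed capture-history file (bad row length, non-binary symbol...)."""


@dataclass
class CaptureData:
    """Binary capture histories with robust-design period structure.

    Parameters
    ----------
    individuals : ordered individual identifiers (length N_obs).
    occasions : ordered occasion labels, strictly increasing in time.
    matrix : (N_obs, t) array of 0/1 detections.
    primary_of : occasion label -> primary-period label. Defaults to a single
        period ``"1"``. Periods must form contiguous blocks of occasions.
    covariates : per-individual attributes (e.g. ``site``, ``age``), indexed
        by individual identifier.
    birth_period : individual -> primary period of first possible presence
        (recorded for juveniles; used by the reference-population rules).
    """

    individuals: list[str]
    occasions: list[str]
    matrix: np.ndarray
    primary_of: dict[str, str] = field(default_factory=dict)
    covariates: pd.DataFrame | None = None
    birth_period: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.individuals = [str(i) for i in self.individuals]
        self.occasions = [str(o) for o in self.occasions]
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if not self.primary_of:
            self.primary_of = {o: "1" for o in self.occasions}
        self._validate()

    def _validate(self) -> None:
        n_ind, n_occ = len(self.individuals), len(self.occasions)
        if n_ind == 0:
            raise ValueError("capture data must contain at least one individual")
        if self.matrix.shape != (n_ind, n_occ):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{n_ind} individuals x {n_occ} occasions"
            )
        if not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("matrix entries must be 0 or 1")
        if (self.matrix.sum(axis=1) == 0).any():
            bad = [i for i, r in zip(self.individuals, self.matrix) if r.sum() == 0]
            raise ValueError(f"individuals with all-zero histories: {bad}")
        if len(set(self.individuals)) != n_ind:
            raise ValueError("duplicate individual identifiers")
        missing = [o for o in self.occasions if o not in self.primary_of]
        if missing:
            raise ValueError(f"occasions without a primary period: {missing}")
        # primary periods must be contiguous blocks in occasion order
        seen: list[str] = []
        for o in self.occasions:
            p = self.primary_of[o]
            if seen and seen[-1] != p and p in seen:
                raise ValueError(f"primary period {p!r} is not contiguous")
            if not seen or seen[-1] != p:
                seen.append(p)
        self._period_order = seen

    # -- structure ---------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_occasions(self) -> int:
        return len(self.occasions)

    @property
    def primary_periods(self) -> list[str]:
        """Primary-period labels in calendar order."""
        return list(self._period_order)

    def occasions_of(self, period: str) -> list[str]:
        return [o for o in self.occasions if self.primary_of[o] == period]

    def occasion_captures(self) -> np.ndarray:
        """Total detections per occasion (column sums)."""
        return self.matrix.sum(axis=0)

    def distinct_in(self, occasions: Sequence[str]) -> set[str]:
        """Identifiers of individuals detected at least once in *occasions*."""
        idx = [self.occasions.index(o) for o in occasions]
        hit = self.matrix[:, idx].any(axis=1)
        return {i for i, h in zip(self.individuals, hit) if h}

    def history_strings(self) -> list[str]:
        return ["".join(map(str, row)) for row in self.matrix]


@dataclass
class FrequencyData:
    """Capture-frequency summary of one closed sampling block.

    ``f[k-1]`` counts individuals caught exactly k times; ``S = sum(f)`` is the
    number of distinct individuals and ``n = sum(k * f_k)`` the total number of
    detections.  ``t`` (the occasion count) and the per-occasion sample sizes
    ``n_j`` may be unavailable when only a published frequency table is at
    hand; estimators requiring them refuse such data explicitly.
    """

    f: np.ndarray
    t: int | None = None
    n_j: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=np.int64)
        if (self.f < 0).any():
            raise ValueError("capture frequencies must be non-negative")
        if self.t is not None:
            if self.t < len(self.f) and self.f[self.t:].any():
                raise ValueError("nonzero frequency beyond the occasion count")
            if len(self.f) < self.t:
                self.f = np.pad(self.f, (0, self.t - len(self.f)))
        if self.n_j is not None:
            self.n_j = np.asarray(self.n_j, dtype=np.int64)
            if self.n_j.sum() != self.n:
                raise ValueError(
                    f"per-occasion sizes sum to {self.n_j.sum()} but total "
                    f"captures are {self.n}"
                )

    @property
    def S(self) -> int:
        """Number of distinct individuals captured."""
        return int(self.f.sum())

    @property
    def n(self) -> int:
        """Total number of detections."""
        k = np.arange(1, len(self.f) + 1)
        return int((k * self.f).sum())

    def require_occasions(self, what: str) -> None:
        if self.t is None:
            raise ValueError(f"{what} needs occasion count t, which is unknown")

    def require_sample_sizes(self, what: str) -> None:
        if self.n_j is None:
            raise ValueError(f"{what} needs occasion-level data (n_j absent)")


# -- I/O -------------------------------------------------------------------


def _read_design(design) -> dict:
    if design is None:
        return {}
    if isinstance(design, (str, Path)):
        with open(design) as fh:
            return yaml.safe_load(fh) or {}
    return dict(design)


def read_capture_data(source, format: str = "csv", design=None) -> CaptureData:
    """Read capture histories from ``csv`` or MARK ``.inp``.

    *design* is an optional mapping (or YAML path) with keys ``primary_of``,
    ``covariates`` and ``birth_period``; individuals with all-zero histories
    are rejected.
    """
    design = _read_design(design)
    if format == "csv":
        individuals, occasions, matrix = _read_csv(source)
    elif format == "inp":
        individuals, occasions, matrix = _read_inp(source)
    else:
        raise ValueError(f"unknown format {format!r}")
    cov = design.get("covariates")
    cov_df = pd.DataFrame.from_dict(cov, orient="index") if cov else None
    return CaptureData(
        individuals=individuals,
        occasions=occasions,
        matrix=matrix,
        primary_of={str(k): str(v) for k, v in design.get("primary_of", {}).items()},
        covariates=cov_df,
        birth_period={str(k): str(v) for k, v in design.get("birth_period", {}).items()},
    )


def _read_csv(source):
    df = pd.read_csv(source, dtype=str)
    occasions = [str(c) for c in df.columns[1:]]
    individuals = df.iloc[:, 0].astype(str).tolist()
    try:
        matrix = df.iloc[:, 1:].astype(np.int8).to_numpy()
    except ValueError as exc:
        raise CaptureFormatError(f"non-numeric capture indicator: {exc}") from exc
    if not np.isin(matrix, (0, 1)).all():
        i, j = np.argwhere(~np.isin(matrix, (0, 1)))[0]
        raise CaptureFormatError(
            f"non-binary symbol {matrix[i, j]} at row {i + 2} (individual "
            f"{individuals[i]!r})"
        )
    return individuals, occasions, matrix


_INP_COMMENT = re.compile(r"/\*.*?\*/", re.DOTALL)
_INP_RECORD = re.compile(r"^([01]+)\s+(\d+)\s*;$")


def _read_inp(source):
    text = Path(source).read_text()
    text = _INP_COMMENT.sub(" ", text)
    histories: list[str] = []
    width = None
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        m = _INP_RECORD.match(line)
        if not m:
            raise CaptureFormatError(f"malformed .inp record at line {lineno}: {raw!r}")
        hist, freq = m.group(1), int(m.group(2))
        if width is None:
            width = len(hist)
        elif len(hist) != width:
            raise CaptureFormatError(
                f"history length {len(hist)} != {width} at line {lineno}"
            )
        histories.extend([hist] * freq)
    if not histories:
        raise CaptureFormatError("no encounter histories found")
    matrix = np.array([[int(c) for c in h] for h in histories], dtype=np.int8)
    individuals = [f"ind{i + 1:04d}" for i in range(len(histories))]
    occasions = [str(j + 1) for j in range(width)]
    return individuals, occasions, matrix


def write_capture_data(data: CaptureData, path, format: str = "csv") -> None:
    """Write histories as CSV (with YAML design sidecar) or MARK ``.inp``.

    CSV round-trips exactly. ``.inp`` groups identical histories into one
    ``history frequency;`` record (first-appearance order) and drops
    identifiers, so it round-trips the history multiset, not the row labels.
    """
    path = Path(path)
    if format == "csv":
        df = pd.DataFrame(data.matrix, columns=data.occasions)
        df.insert(0, "id", data.individuals)
        df.to_csv(path, index=False)
        design: dict = {"primary_of": dict(data.primary_of)}
        if data.birth_period:
            design["birth_period"] = dict(data.birth_period)
        if data.covariates is not None:
            design["covariates"] = {
                str(i): {k: v for k, v in row.items() if pd.notna(v)}
                for i, row in data.covariates.to_dict(orient="index").items()
            }
        path.with_suffix(path.suffix + ".yaml").write_text(
            yaml.safe_dump(design, sort_keys=False)
        )
    elif format == "inp":
        counts: dict[str, int] = {}
        for h in data.history_strings():
            counts[h] = counts.get(h, 0) + 1
        lines = [f"{h} {c};" for h, c in counts.items()]
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


# -- transformations -------------------------------------------------------


def pool_occasions(data: CaptureData, grouping: Iterable[Sequence[str]]) -> CaptureData:
    """Merge groups of contiguous same-period occasions into single occasions.

    The pooled detection indicator is 1 iff the individual was caught on any
    member occasion (samples are sets of distinct animals, as Petersen
    arithmetic requires).  Occasions not mentioned in *grouping* are kept as
    singletons.  Groups spanning periods or non-contiguous occasions are
    rejected.
    """
    groups = [list(map(str, g)) for g in grouping]
    grouped = [o for g in groups for o in g]
    if len(grouped) != len(set(grouped)):
        raise ValueError("an occasion appears in more than one group")
    unknown = set(grouped) - set(data.occasions)
    if unknown:
        raise ValueError(f"unknown occasions in grouping: {sorted(unknown)}")
    for g in groups:
        idx = sorted(data.occasions.index(o) for o in g)
        if idx != list(range(idx[0], idx[-1] + 1)):
            raise ValueError(f"group {g} is not contiguous in time")
        periods = {data.primary_of[o] for o in g}
        if len(periods) > 1:
            raise ValueError(f"group {g} crosses primary periods {sorted(periods)}")
    by_start = {min(data.occasions.index(o) for o in g): g for g in groups}
    new_occasions: list[str] = []
    new_primary: dict[str, str] = {}
    cols: list[np.ndarray] = []
    j = 0
    while j < data.n_occasions:
        if j in by_start:
            g = by_start[j]
            idx = [data.occasions.index(o) for o in g]
            label = "+".join(data.occasions[i] for i in sorted(idx))
            cols.append(data.matrix[:, idx].max(axis=1))
            j = max(idx) + 1
        else:
            label = data.occasions[j]
            cols.append(data.matrix[:, j])
            j += 1
        if label in new_primary:
            raise ValueError(f"pooled occasion label {label!r} is not unique")
        new_occasions.append(label)
        new_primary[label] = data.primary_of[label.split("+")[0]]
    return replace(
        data,
        occasions=new_occasions,
        matrix=np.column_stack(cols),
        primary_of=new_primary,
    )


def capture_frequencies(data: CaptureData) -> FrequencyData:
    """Reduce histories to capture frequencies f_1..f_t with per-occasion n_j."""
    if data.n_occasions < 1:
        raise ValueError("need at least one occasion")
    counts = data.matrix.sum(axis=1)
    t = data.n_occasions
    f = np.bincount(counts, minlength=t + 1)[1:]
    return FrequencyData(f=f, t=t, n_j=data.occasion_captures())


def restrict_to_period(data: CaptureData, period: str) -> CaptureData:
    """Keep only one primary period's occasions; drop individuals unseen in it."""
    period = str(period)
    if period not in data.primary_periods:
        raise ValueError(f"unknown primary period {period!r}")
    occ_idx = [j for j, o in enumerate(data.occasions) if data.primary_of[o] == period]
    sub = data.matrix[:, occ_idx]
    keep = sub.sum(axis=1) > 0
    individuals = [i for i, k in zip(data.individuals, keep) if k]
    cov = data.covariates.loc[individuals] if data.covariates is not None else None
    return CaptureData(
        individuals=individuals,
        occasions=[data.occasions[j] for j in occ_idx],
        matrix=sub[keep],
        primary_of={data.occasions[j]: period for j in occ_idx},
        covariates=cov,
        birth_period={i: p for i, p in data.birth_period.items() if i in set(individuals)},
    )
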