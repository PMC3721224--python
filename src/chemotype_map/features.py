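"""Per-sample GC/MS peak tables to a cross-sample feature matrix.

Each chromatogram is reduced to peaks (retention time, height, optional base
mass and isotope envelope).  Heights are expressed relative to the most
abundant peak of the same chromatogram (base-peak-relative, %), peaks below a
relative-height threshold or outside the retention-time window are dropped,
and the retained peaks are binned across samples by retention time (and base
mass when available) into recurring features.  The result is a samples x
features matrix of relative heights with zeros for absence — the input to
Bray-Curtis chemotyping.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Peak",
    "SampleRun",
    "FeatureError",
    "normalize_heights",
    "filter_peaks",
    "prepare_run",
    "match_features",
    "read_peak_table",
    "write_peak_table",
    "read_feature_table",
    "write_feature_table",
]

DEFAULT_THRESHOLD_PCT = 10.0
DEFAULT_RT_WINDOW = (10.0, 30.0)
DEFAULT_RT_TOL_MIN = 0.10
DEFAULT_MASS_TOL_AMU = 1.0


class FeatureError(ValueError):
    """Raised for invalid peak data or malformed peak/feature tables."""


@dataclass
class Peak:
    """A single chromatographic peak.

    ``height`` is in arbitrary detector counts on input and in base-peak
    percent after :func:`normalize_heights` has been applied via
    :func:`prepare_run`.
    """

    rt: float
    height: float
    base_mass: float | None = None
    envelope: list[float] | None = None

    def __post_init__(self) -> None:
        if not (self.rt > 0 and math.isfinite(self.rt)):
            raise FeatureError(f"retention time must be positive, got {self.rt}")
        if not (self.height > 0 and math.isfinite(self.height)):
            raise FeatureError(f"peak height must be positive, got {self.height}")


@dataclass
class SampleRun:
    """All peaks of one sample's chromatogram."""

    sample_id: str
    peaks: list[Peak] = field(default_factory=list)


def normalize_heights(run: SampleRun) -> list[float]:
    """Base-peak-relative heights (%) for every peak of a run.

    The most abundant peak maps to exactly 100; ties all map to 100.
    """
    if not run.peaks:
        raise FeatureError(f"sample {run.sample_id!r} has no peaks")
    top = max(p.height for p in run.peaks)
    # divide before scaling so the base peak maps to exactly 100.0
    return [100.0 * (p.height / top) for p in run.peaks]


def filter_peaks(
    run: SampleRun,
    relative_heights: Sequence[float],
    threshold: float = DEFAULT_THRESHOLD_PCT,
    rt_window: tuple[float, float] = DEFAULT_RT_WINDOW,
) -> SampleRun:
    """Retain peaks strictly above ``threshold`` % and inside the closed rt window.

    Returns a new run whose peak heights are the retained relative heights.
    """
    if not (0 < threshold < 100):
        raise FeatureError(f"threshold must be in (0, 100), got {threshold}")
    lo, hi = rt_window
    kept = [
        Peak(p.rt, rel, p.base_mass, p.envelope)
        for p, rel in zip(run.peaks, relative_heights)
        if rel > threshold and lo <= p.rt <= hi
    ]
    return SampleRun(run.sample_id, kept)


def prepare_run(
    run: SampleRun,
    threshold: float = DEFAULT_THRESHOLD_PCT,
    rt_window: tuple[float, float] = DEFAULT_RT_WINDOW,
) -> SampleRun:
    """Normalise then filter a run (the per-sample preprocessing step)."""
    return filter_peaks(run, normalize_heights(run), threshold, rt_window)


class _Bin:
    __slots__ = ("rts", "masses", "members", "order")

    def __init__(self, order: int) -> None:
        self.rts: list[float] = []
        self.masses: list[float] = []
        self.members: dict[str, Peak] = {}
        self.order = order

    @property
    def consensus_rt(self) -> float:
        return sum(self.rts) / len(self.rts)

    @property
    def consensus_mass(self) -> float | None:
        return sum(self.masses) / len(self.masses) if self.masses else None

    def add(self, sample_id: str, peak: Peak) -> None:
        self.rts.append(peak.rt)
        if peak.base_mass is not None:
            self.masses.append(peak.base_mass)
        self.members[sample_id] = peak

    def matches(self, peak: Peak, rt_tol: float, mass_tol: float) -> bool:
        if abs(peak.rt - self.consensus_rt) > rt_tol:
            return False
        cm = self.consensus_mass
        if peak.base_mass is not None and cm is not None:
            return abs(peak.base_mass - cm) <= mass_tol
        return True


def match_features(
    runs: Sequence[SampleRun],
    rt_tol: float = DEFAULT_RT_TOL_MIN,
    mass_tol: float = DEFAULT_MASS_TOL_AMU,
    min_occurrence: int = 1,
) -> pd.DataFrame:
    """Bin peaks across samples into recurring features.

    Peaks (already normalised and filtered) are processed in global
    (rt, base_mass, sample_id) order and greedily joined to the nearest
    existing bin whose consensus retention time is within ``rt_tol`` and, when
    both masses are known, whose consensus base mass is within ``mass_tol``.
    A bin holds at most one peak per sample: on collision the peak closer to
    the bin's consensus rt stays and the other seeds a new bin.  The ordering
    makes the outcome independent of the order samples are supplied in.

    Returns a DataFrame indexed by sample_id (input order) with feature
    columns named ``rt<minutes>_m<mass>`` ordered by consensus rt, zeros where
    a sample lacks the feature.  Features seen in fewer than
    ``min_occurrence`` samples are dropped.
    """
    sample_ids = [r.sample_id for r in runs]
    if len(set(sample_ids)) != len(sample_ids):
        raise FeatureError("duplicate sample ids")

    pool = [
        (p.rt, p.base_mass if p.base_mass is not None else math.inf, r.sample_id, p)
        for r in runs
        for p in r.peaks
    ]
    pool.sort(key=lambda t: t[:3])

    bins: list[_Bin] = []
    for _, _, sid, peak in pool:
        candidates = [b for b in bins if b.matches(peak, rt_tol, mass_tol)]
        candidates.sort(key=lambda b: (abs(peak.rt - b.consensus_rt), b.order))
        placed = False
        for b in candidates:
            if sid not in b.members:
                b.add(sid, peak)
                placed = True
                break
        if placed:
            continue
        if candidates:
            # every matching bin already holds this sample: closest rt wins
            b = candidates[0]
            incumbent = b.members[sid]
            if abs(peak.rt - b.consensus_rt) < abs(incumbent.rt - b.consensus_rt):
                b.members[sid] = peak
                b.rts.append(peak.rt)
                if peak.base_mass is not None:
                    b.masses.append(peak.base_mass)
                peak = incumbent  # displaced peak seeds a new bin
        nb = _Bin(len(bins))
        nb.add(sid, peak)
        bins.append(nb)

    bins = [b for b in bins if len(b.members) >= min_occurrence]
    bins.sort(key=lambda b: (b.consensus_rt, b.consensus_mass or math.inf))

    columns = []
    values = np.zeros((len(runs), len(bins)))
    for j, b in enumerate(bins):
        cm = b.consensus_mass
        columns.append(
            f"rt{b.consensus_rt:.2f}" + (f"_m{cm:.0f}" if cm is not None else "")
        )
        for sid, peak in b.members.items():
            values[sample_ids.index(sid), j] = peak.height
    return pd.DataFrame(values, index=pd.Index(sample_ids, name="sample_id"), columns=columns)


# ---------------------------------------------------------------------------
# I/O

_PEAK_COLUMNS = ["sample_id", "rt_min", "height", "base_mass", "envelope"]


def read_peak_table(path) -> list[SampleRun]:
    """Read a long-format peak-table CSV into one SampleRun per sample.

    Columns: sample_id, rt_min, height, optional base_mass, optional envelope
    (semicolon-joined abundances).  Sample order follows first appearance.
    """
    runs: dict[str, SampleRun] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "sample_id" not in reader.fieldnames:
            raise FeatureError(f"{path}: missing header with sample_id column")
        for i, row in enumerate(reader, start=2):
            try:
                env_raw = (row.get("envelope") or "").strip()
                peak = Peak(
                    rt=float(row["rt_min"]),
                    height=float(row["height"]),
                    base_mass=float(row["base_mass"]) if row.get("base_mass") else None,
                    envelope=[float(v) for v in env_raw.split(";")] if env_raw else None,
                )
            except (KeyError, ValueError) as exc:
                raise FeatureError(f"{path}: malformed peak row at line {i}: {exc}") from exc
            runs.setdefault(row["sample_id"], SampleRun(row["sample_id"])).peaks.append(peak)
    return list(runs.values())


def write_peak_table(path, runs: Iterable[SampleRun]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_PEAK_COLUMNS)
        for run in runs:
            for p in run.peaks:
                writer.writerow(
                    [
                        run.sample_id,
                        repr(float(p.rt)),
                        repr(float(p.height)),
                        "" if p.base_mass is None else repr(float(p.base_mass)),
                        ";".join(repr(float(a)) for a in p.envelope) if p.envelope else "",
                    ]
                )


def write_feature_table(path, table: pd.DataFrame) -> None:
    """Write a feature table (samples as rows) losslessly to CSV.

    Values are serialised with full-precision reprs so a write/read cycle is
    bit-exact.
    """
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", *table.columns])
        for sid, row in table.iterrows():
            writer.writerow([sid, *(repr(float(v)) for v in row)])


def read_feature_table(path) -> pd.DataFrame:
    try:
        table = pd.read_csv(path, index_col="sample_id", float_precision="round_trip")
    except (ValueError, pd.errors.ParserError) as exc:
        raise FeatureError(f"{path}: malformed feature table: {exc}") from exc
    table.index = table.index.astype(str)
    return table.astype(float)
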