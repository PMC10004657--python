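"""Cleaning of raw intraoperative blood-pressure records.

Anesthesia records mix invasive (15-s or 2-min) and oscillometric
(every 3-5 min) pressure samples and contain transducer/cuff artifacts.
This module applies six artifact-rejection rules and resamples each
surgery's mean arterial pressure (MAP) onto a uniform 15-s grid, which
is the substrate for every hypotension characterization downstream.

The six rules, applied per surgery:

1. systolic >= 300 mmHg
2. systolic <= 20 mmHg
3. diastolic <= 5 mmHg
4. diastolic >= 225 mmHg
5. systolic <= diastolic + 5 mmHg
6. any channel (SBP, DBP, MAP) outside mean +/- 3 SD of the surgery's
   remaining samples after rules 1-5

Rules 1-5 are pointwise predicates on raw values; rule 6 is a single
pass (not iterated) using the post-rules-1-5 per-channel moments,
evaluated leave-one-out (the sample being judged is excluded from the
mean/SD so one gross artifact cannot mask itself in short records).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

GRID_STEP_S = 15.0

RULE_NAMES = {
    1: "sbp_ge_300",
    2: "sbp_le_20",
    3: "dbp_le_5",
    4: "dbp_ge_225",
    5: "sbp_le_dbp_plus_5",
    6: "outside_3sd",
}


class BPSample(NamedTuple):
    """One pressure observation; missing channels are None/NaN."""

    t: float
    sbp: float | None = None
    dbp: float | None = None
    map: float | None = None
    source: str = "non_invasive"


@dataclass
class BPSeries:
    """One surgery's time-ordered pressure samples (vectorized storage).

    ``t`` is seconds from anesthesia start; ``sbp``/``dbp``/``map`` are
    mmHg with NaN for missing channels; ``anesthesia_end_s`` bounds the
    record (>= last sample time).
    """

    case_id: str
    t: np.ndarray
    sbp: np.ndarray
    dbp: np.ndarray
    map: np.ndarray
    source: str = "non_invasive"
    anesthesia_end_s: float = 0.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.sbp = np.asarray(self.sbp, dtype=float)
        self.dbp = np.asarray(self.dbp, dtype=float)
        self.map = np.asarray(self.map, dtype=float)
        if len(self.t) and np.any(np.diff(self.t) <= 0):
            raise ValueError(f"case {self.case_id}: sample times must be strictly increasing")
        if len(self.t) and self.t[0] < 0:
            raise ValueError(f"case {self.case_id}: negative sample time")
        if self.anesthesia_end_s == 0.0 and len(self.t):
            self.anesthesia_end_s = float(self.t[-1])
        if len(self.t) and self.anesthesia_end_s < self.t[-1]:
            raise ValueError(f"case {self.case_id}: anesthesia_end_s before last sample")

    def __len__(self) -> int:
        return len(self.t)

    def sample(self, i: int) -> BPSample:
        def _v(x):
            return None if np.isnan(x) else float(x)

        return BPSample(float(self.t[i]), _v(self.sbp[i]), _v(self.dbp[i]),
                        _v(self.map[i]), self.source)


@dataclass
class MapGrid:
    """Uniform 15-s MAP grid for one surgery; no missing values."""

    case_id: str
    values: np.ndarray
    step_s: float = GRID_STEP_S

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(~np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValueError(f"case {self.case_id}: grid has non-positive or missing MAP")

    @property
    def n_points(self) -> int:
        return len(self.values)

    @property
    def duration_min(self) -> float:
        """Record span in minutes, counting each point as one 15-s slot."""
        return self.n_points * self.step_s / 60.0


@dataclass
class ArtifactReport:
    case_id: str
    n_samples: int
    rule_hits: dict[int, np.ndarray] = field(default_factory=dict)
    counts: dict[int, int] = field(default_factory=dict)
    n_removed: int = 0

    @property
    def fraction_removed(self) -> float:
        return self.n_removed / self.n_samples if self.n_samples else 0.0


class EmptySeriesError(ValueError):
    """All samples of a surgery were rejected as artifacts."""


def derive_map(sample: BPSample) -> float:
    """MAP for one sample: recorded value if present, else DBP + PP/3.

    Oscillometric devices measure MAP directly (systolic/diastolic are
    derived quantities), so a recorded MAP channel always wins.
    """
    if sample.map is not None and not (isinstance(sample.map, float) and np.isnan(sample.map)):
        return float(sample.map)
    if sample.sbp is None or sample.dbp is None:
        raise ValueError("no derivable MAP: need recorded MAP or both SBP and DBP")
    return float(sample.dbp + (sample.sbp - sample.dbp) / 3.0)


def _derived_map_array(series: BPSeries) -> np.ndarray:
    """Vectorized derive_map over a series; NaN where underivable."""
    out = series.map.copy()
    need = np.isnan(out)
    both = need & ~np.isnan(series.sbp) & ~np.isnan(series.dbp)
    out[both] = series.dbp[both] + (series.sbp[both] - series.dbp[both]) / 3.0
    return out


def remove_artifacts(series: BPSeries) -> tuple[BPSeries, ArtifactReport]:
    """Apply the six rejection rules to one surgery's record.

    Returns the cleaned series and a per-rule report. A sample may hit
    several rules; it is removed once but counted under each rule.
    Raises :class:`EmptySeriesError` if nothing survives.
    """
    if len(series) == 0:
        raise EmptySeriesError(f"case {series.case_id}: empty series")
    sbp, dbp = series.sbp, series.dbp
    with np.errstate(invalid="ignore"):  # NaN comparisons are False: missing channel never hits
        hits = {
            1: sbp >= 300,
            2: sbp <= 20,
            3: dbp <= 5,
            4: dbp >= 225,
            5: sbp <= dbp + 5,
        }
    raw_bad = hits[1] | hits[2] | hits[3] | hits[4] | hits[5]

    # rule 6: per-channel 3-SD screen against the post-rules-1-5 moments,
    # computed leave-one-out so a gross artifact cannot inflate the SD it
    # is judged against (indistinguishable from pooled moments at scale)
    keep15 = ~raw_bad
    map_arr = _derived_map_array(series)
    hit6 = np.zeros(len(series), dtype=bool)
    for chan in (sbp, dbp, map_arr):
        use = keep15 & ~np.isnan(chan)
        ref = chan[use]
        n = len(ref)
        if n < 3:
            continue
        s, ss = float(ref.sum()), float((ref**2).sum())
        x = chan[use]
        mean_loo = (s - x) / (n - 1)
        var_loo = np.clip((ss - x**2) / (n - 1) - mean_loo**2, 0.0, None)
        dev = np.abs(x - mean_loo) > 3.0 * np.sqrt(var_loo)
        idx = np.flatnonzero(use)
        hit6[idx[dev]] = True
    hits[6] = hit6

    removed = raw_bad | hit6
    keep = ~removed
    report = ArtifactReport(
        case_id=series.case_id,
        n_samples=len(series),
        rule_hits=hits,
        counts={r: int(h.sum()) for r, h in hits.items()},
        n_removed=int(removed.sum()),
    )
    if not keep.any():
        raise EmptySeriesError(f"case {series.case_id}: all samples removed as artifacts")
    clean = BPSeries(
        case_id=series.case_id,
        t=series.t[keep],
        sbp=sbp[keep],
        dbp=dbp[keep],
        map=series.map[keep],
        source=series.source,
        anesthesia_end_s=series.anesthesia_end_s,
    )
    return clean, report


class UnusableSeriesError(ValueError):
    """Fewer than two clean samples: cannot interpolate."""


def interpolate_to_grid(series: BPSeries, step_s: float = GRID_STEP_S) -> MapGrid:
    """Linearly interpolate a clean series' MAP onto t = 0, step, 2*step, ...

    Before the first and after the last observation the nearest observed
    value is held constant (no trend extrapolation). The grid runs from
    t = 0 to anesthesia_end_s.
    """
    map_vals = _derived_map_array(series)
    ok = ~np.isnan(map_vals)
    t, v = series.t[ok], map_vals[ok]
    if len(t) < 2:
        raise UnusableSeriesError(f"case {series.case_id}: <2 samples with derivable MAP")
    n = int(np.floor(series.anesthesia_end_s / step_s)) + 1
    grid_t = np.arange(n) * step_s
    grid_v = np.interp(grid_t, t, v)  # np.interp holds endpoint values
    return MapGrid(case_id=series.case_id, values=grid_v, step_s=step_s)


def preprocess_series(series: BPSeries, step_s: float = GRID_STEP_S) -> tuple[MapGrid, ArtifactReport]:
    """remove_artifacts then interpolate_to_grid for one surgery."""
    clean, report = remove_artifacts(series)
    return interpolate_to_grid(clean, step_s=step_s), report
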