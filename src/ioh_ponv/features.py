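"""Hypotension exposure characterizations of a gridded MAP trace.

Four families summarize intraoperative hypotension (IOH) as one scalar
per surgery:

- ``sustained_lowest`` (mmHg): the lowest ceiling under which MAP stayed
  for k *contiguous* minutes — min over all windows spanning k minutes
  of the window maximum.
- ``cumulative_lowest`` (mmHg): the lowest observed MAP value v such
  that total (possibly non-contiguous) time with MAP <= v reaches k
  minutes — the m-th smallest grid value, m = ceil(k*60/step).
- ``time_under`` (minutes): absolute time with MAP strictly below a
  threshold, counted as 15-s grid slots.
- ``fraction_under`` (unitless): time_under divided by the gridded
  record span.

Conventions: "under" a threshold is strict ``<``; the sustained/
cumulative ceiling is inclusive ``<=`` ("stayed at or below"); a
sustained window of k minutes spans k*60/step + 1 grid points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .preprocess import MapGrid

SUSTAINED_MINUTES = (1, 3, 5, 10, 15)
CUMULATIVE_MINUTES = (1, 3, 5, 10, 15)
THRESHOLDS_MMHG = (50, 55, 60, 65, 70, 75, 80)

_FAMILIES = ("sustained_lowest", "cumulative_lowest", "time_under", "fraction_under")
_ZERO_INFLATED_FAMILIES = ("time_under", "fraction_under")


@dataclass(frozen=True)
class CharacterizationSpec:
    """One IOH exposure metric: a family plus its parameter.

    ``param`` is minutes (k) for the lowest-MAP families and a MAP
    threshold in mmHg for the time-under families.
    """

    family: str
    param: float

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown characterization family: {self.family}")

    @property
    def label(self) -> str:
        p = self.param
        p_str = str(int(p)) if float(p).is_integer() else str(p).replace(".", "p")
        return f"{self.family}_{p_str}"

    @property
    def zero_inflated(self) -> bool:
        """Families with a point mass at zero (no hypotension at all)."""
        return self.family in _ZERO_INFLATED_FAMILIES

    @classmethod
    def from_label(cls, label: str) -> "CharacterizationSpec":
        for fam in _FAMILIES:
            if label.startswith(fam + "_"):
                return cls(fam, float(label[len(fam) + 1:].replace("p", ".")))
        raise ValueError(f"cannot parse characterization label: {label}")


def default_specs() -> list[CharacterizationSpec]:
    """The full grid of characterizations (5 + 5 + 7 + 7 = 24)."""
    specs = [CharacterizationSpec("sustained_lowest", k) for k in SUSTAINED_MINUTES]
    specs += [CharacterizationSpec("cumulative_lowest", k) for k in CUMULATIVE_MINUTES]
    specs += [CharacterizationSpec("time_under", thr) for thr in THRESHOLDS_MMHG]
    specs += [CharacterizationSpec("fraction_under", thr) for thr in THRESHOLDS_MMHG]
    return specs


def lowest_sustained_map(grid: MapGrid, k_minutes: float) -> float:
    """Lowest MAP held for k sustained minutes, NaN if the record is shorter.

    A window of m = k*60/step + 1 consecutive points spans exactly k
    minutes; the metric is min over window starts of the window max.
    """
    m = int(round(k_minutes * 60.0 / grid.step_s)) + 1
    v = grid.values
    if len(v) < m:
        return float("nan")
    return float(sliding_window_view(v, m).max(axis=1).min())


def lowest_cumulative_map(grid: MapGrid, k_minutes: float) -> float:
    """Lowest MAP value v with >= k total minutes at or below v.

    Equals the m-th smallest grid value with m = ceil(k*60/step), since
    each grid point accounts for one step of time.
    """
    m = int(math.ceil(k_minutes * 60.0 / grid.step_s))
    v = grid.values
    if len(v) < m or m < 1:
        return float("nan") if len(v) < m else float(v.min())
    return float(np.partition(v, m - 1)[m - 1])


def time_under(grid: MapGrid, threshold: float) -> float:
    """Minutes with MAP strictly below ``threshold`` (15-s slot counting)."""
    return float((grid.values < threshold).sum()) * grid.step_s / 60.0


def fraction_under(grid: MapGrid, threshold: float) -> float:
    """Share of the gridded record spent with MAP strictly below ``threshold``."""
    return time_under(grid, threshold) / grid.duration_min


def compute_exposure(grid: MapGrid, spec: CharacterizationSpec) -> float:
    """Evaluate one characterization on one grid (NaN when undefined)."""
    if spec.family == "sustained_lowest":
        return lowest_sustained_map(grid, spec.param)
    if spec.family == "cumulative_lowest":
        return lowest_cumulative_map(grid, spec.param)
    if spec.family == "time_under":
        return time_under(grid, spec.param)
    return fraction_under(grid, spec.param)


def compute_feature_table(
    grids: Iterable[MapGrid] | Mapping[str, MapGrid],
    specs: list[CharacterizationSpec],
) -> pd.DataFrame:
    """Exposure table: one row per surgery, one column per characterization.

    Undefined values (record shorter than k minutes) propagate as NaN.
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    if isinstance(grids, Mapping):
        grids = grids.values()
    rows = {}
    for grid in grids:
        rows[grid.case_id] = [compute_exposure(grid, s) for s in specs]
    table = pd.DataFrame.from_dict(rows, orient="index", columns=[s.label for s in specs])
    table.index.name = "case_id"
    return table


def summarize_features(table: pd.DataFrame) -> pd.DataFrame:
    """Median (Q1, Q3) and missing count per characterization column."""
    out = pd.DataFrame({
        "median": table.median(),
        "q1": table.quantile(0.25),
        "q3": table.quantile(0.75),
        "n_undefined": table.isna().sum(),
    })
    out.index.name = "characterization"
    return out
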