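"""Dive-profile context for call production.

Relates calls to the tag's pressure record: depth at call time (linear
interpolation of the 5 Hz depth series), dive segmentation (a dive is an
excursion below the 2 m surface threshold lasting at least 10 s), per-dive
maximum depths, and surface-call statistics.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

SURFACE_THRESHOLD_M = 2.0
MIN_DIVE_DURATION_S = 10.0

__all__ = [
    "DepthSeries",
    "Dive",
    "depth_at",
    "find_dives",
    "call_depth_summary",
    "OutOfRangeError",
]


class OutOfRangeError(ValueError):
    """Query time outside the depth series span."""


@dataclass
class DepthSeries:
    """Uniformly sampled depth (m, positive down) for one tag."""

    tag_id: str
    times: np.ndarray
    depths: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.depths = np.asarray(self.depths, dtype=float)
        if self.times.size != self.depths.size:
            raise ValueError("times and depths must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times.size and float(self.depths.min()) < -0.5:
            raise ValueError("depths below -0.5 m exceed sensor-noise tolerance")
        # small negative sensor noise is clamped for all downstream use
        self.depths = np.clip(self.depths, 0.0, None)

    @property
    def t_start(self) -> float:
        return float(self.times[0])

    @property
    def t_end(self) -> float:
        return float(self.times[-1])


@dataclass
class Dive:
    """One excursion below the surface threshold."""

    tag_id: str
    t_start: float
    t_end: float
    max_depth: float


def depth_at(series: DepthSeries, t) -> float | np.ndarray:
    """Depth at time ``t`` by linear interpolation between samples."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < series.t_start) or np.any(t_arr > series.t_end):
        raise OutOfRangeError(
            f"time outside depth record [{series.t_start}, {series.t_end}]"
        )
    out = np.interp(t_arr, series.times, series.depths)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def find_dives(
    series: DepthSeries,
    surface_threshold: float = SURFACE_THRESHOLD_M,
    min_duration: float = MIN_DIVE_DURATION_S,
) -> list[Dive]:
    """Maximal intervals with depth >= threshold lasting >= ``min_duration``."""
    deep = series.depths >= surface_threshold
    dives: list[Dive] = []
    i = 0
    n = deep.size
    while i < n:
        if deep[i]:
            j = i
            while j + 1 < n and deep[j + 1]:
                j += 1
            t0, t1 = series.times[i], series.times[j]
            if t1 - t0 >= min_duration:
                dives.append(
                    Dive(
                        tag_id=series.tag_id,
                        t_start=float(t0),
                        t_end=float(t1),
                        max_depth=float(series.depths[i : j + 1].max()),
                    )
                )
            i = j + 1
        else:
            i += 1
    return dives


def call_depth_summary(
    call_depths: pd.DataFrame,
    dives_by_whale: Optional[Mapping[str, Sequence[Dive]]] = None,
    surface_threshold: float = SURFACE_THRESHOLD_M,
) -> tuple[dict, pd.DataFrame]:
    """Pooled and per-whale depth-of-call statistics.

    ``call_depths`` needs columns ``whale_id`` and ``depth_m`` (depth at the
    call's start time).  A call is a surface call iff its depth is below
    ``surface_threshold``.  Returns ``(pooled, per_whale)``; the per-whale
    table carries each whale's maximum dive depth when dives are supplied.
    """
    df = call_depths
    n = len(df)
    pooled = {
        "n_calls": n,
        "n_surface": int((df["depth_m"] < surface_threshold).sum()) if n else 0,
        "frac_surface": float((df["depth_m"] < surface_threshold).mean()) if n else float("nan"),
        "min_depth_m": float(df["depth_m"].min()) if n else float("nan"),
        "mean_depth_m": float(df["depth_m"].mean()) if n else float("nan"),
        "max_depth_m": float(df["depth_m"].max()) if n else float("nan"),
    }
    rows = []
    for whale_id, grp in df.groupby("whale_id", sort=True):
        max_dive = float("nan")
        if dives_by_whale and whale_id in dives_by_whale:
            dives = list(dives_by_whale[whale_id])
            if dives:
                max_dive = max(d.max_depth for d in dives)
        rows.append(
            {
                "whale_id": whale_id,
                "n_calls": len(grp),
                "n_surface": int((grp["depth_m"] < surface_threshold).sum()),
                "frac_surface": float((grp["depth_m"] < surface_threshold).mean()),
                "mean_depth_m": float(grp["depth_m"].mean()),
                "max_call_depth_m": float(grp["depth_m"].max()),
                "max_dive_depth_m": max_dive,
            }
        )
    return pooled, pd.DataFrame(rows)
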