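"""File formats: Raven-style selection tables, WAV, depth CSV, group manifest.

Times inside selection tables and depth files are file-relative seconds;
each tag's per-manifest ``clock_offset`` shifts them onto the shared scene
clock when read.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

from .assign import Detection
from .dive import DepthSeries

SELECTION_REQUIRED = ["Begin Time (s)", "End Time (s)"]
SELECTION_COLUMNS = [
    "Selection",
    "Begin Time (s)",
    "End Time (s)",
    "Low Freq (Hz)",
    "High Freq (Hz)",
    "Noise Flag",
]

__all__ = [
    "SelectionTableError",
    "read_selection_table",
    "write_selection_table",
    "read_depth_csv",
    "write_depth_csv",
    "read_wav",
    "write_wav",
    "TagEntry",
    "GroupManifest",
    "load_manifest",
    "save_manifest",
]


class SelectionTableError(ValueError):
    """Malformed selection table."""


_TRUTHY = {"1", "1.0", "true", "yes", "y"}


def _parse_noise_flag(value) -> bool:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return False
    return str(value).strip().lower() in _TRUTHY


def read_selection_table(
    path, tag_id: str = "", clock_offset: float = 0.0
) -> list[Detection]:
    """Parse a tab-separated Raven-style selection table into detections.

    Requires the ``Begin Time (s)`` / ``End Time (s)`` columns; frequency
    bounds and a noise flag are picked up when present.  Row times are
    shifted by ``clock_offset`` onto the scene clock.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise SelectionTableError(f"{path}: empty file (no header)")
    for col in SELECTION_REQUIRED:
        if col not in df.columns:
            raise SelectionTableError(f"{path}: missing required column {col!r}")
    detections: list[Detection] = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            t0 = float(row["Begin Time (s)"])
            t1 = float(row["End Time (s)"])
        except (TypeError, ValueError):
            raise SelectionTableError(f"{path}: non-numeric time on line {line_no}")
        f_low = f_high = None
        if "Low Freq (Hz)" in df.columns and pd.notna(row["Low Freq (Hz)"]):
            f_low = float(row["Low Freq (Hz)"])
        if "High Freq (Hz)" in df.columns and pd.notna(row["High Freq (Hz)"]):
            f_high = float(row["High Freq (Hz)"])
        noise = _parse_noise_flag(row["Noise Flag"]) if "Noise Flag" in df.columns else False
        if "Selection" in df.columns and pd.notna(row["Selection"]):
            det_id = f"{tag_id}_d{int(float(row['Selection'])) - 1:04d}"
        else:
            det_id = f"{tag_id}_d{idx:04d}"
        detections.append(
            Detection(
                detection_id=det_id,
                tag_id=tag_id,
                t_start=t0 + clock_offset,
                t_end=t1 + clock_offset,
                f_low=f_low,
                f_high=f_high,
                noise_flag=noise,
            )
        )
    return detections


def write_selection_table(path, detections: list[Detection], clock_offset: float = 0.0) -> None:
    """Write detections as a Raven-style table (scene times minus offset)."""
    rows = []
    for k, det in enumerate(detections):
        rows.append(
            {
                "Selection": k + 1,
                "Begin Time (s)": f"{det.t_start - clock_offset:.6f}",
                "End Time (s)": f"{det.t_end - clock_offset:.6f}",
                "Low Freq (Hz)": "" if det.f_low is None else f"{det.f_low:.1f}",
                "High Freq (Hz)": "" if det.f_high is None else f"{det.f_high:.1f}",
                "Noise Flag": 1 if det.noise_flag else 0,
            }
        )
    pd.DataFrame(rows, columns=SELECTION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_depth_csv(path, tag_id: str = "", clock_offset: float = 0.0) -> DepthSeries:
    df = pd.read_csv(path)
    return DepthSeries(
        tag_id=tag_id,
        times=df["time_s"].to_numpy(dtype=float) + clock_offset,
        depths=df["depth_m"].to_numpy(dtype=float),
    )


def write_depth_csv(path, series: DepthSeries) -> None:
    pd.DataFrame({"time_s": series.times, "depth_m": series.depths}).to_csv(
        path, index=False, float_format="%.4f"
    )


def read_wav(path) -> tuple[int, np.ndarray]:
    """Read a WAV file as (fs, float64 samples scaled to full scale = 1.0)."""
    fs, data = wavfile.read(path)
    if data.ndim > 1:
        data = data[:, 0]
    if data.dtype == np.int16:
        samples = data / 32768.0
    elif data.dtype == np.int32:  # 24- or 32-bit PCM
        samples = data / 2147483648.0
    elif data.dtype == np.uint8:
        samples = (data.astype(float) - 128.0) / 128.0
    else:
        samples = data.astype(float)
    return int(fs), samples


def write_wav(path, fs: int, samples: np.ndarray, pcm16: bool = False) -> None:
    """Write float32 (default) or PCM16 WAV."""
    x = np.asarray(samples)
    if pcm16:
        q = np.clip(np.round(x * 32767.0), -32768, 32767)
        wavfile.write(path, int(fs), q.astype(np.int16))
    else:
        wavfile.write(path, int(fs), x.astype(np.float32))


@dataclass
class TagEntry:
    """One tag's files and metadata inside a group manifest."""

    tag_id: str
    whale_id: str
    selections: Optional[str] = None
    wav: Optional[str] = None
    rl_table: Optional[str] = None
    depth: Optional[str] = None
    sensitivity: float = -171.0
    clock_offset: float = 0.0
    sex: Optional[str] = None
    age_class: Optional[str] = None


@dataclass
class GroupManifest:
    """A tagged group: which tag sits on which whale, and the analysis period."""

    group_id: str
    t_start: float
    t_end: float
    tags: list[TagEntry] = field(default_factory=list)
    root: Path = Path(".")

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValueError("analysis period must have positive duration")
        if not self.tags:
            raise ValueError("manifest needs at least one tag")
        tag_ids = [t.tag_id for t in self.tags]
        whale_ids = [t.whale_id for t in self.tags]
        if len(set(tag_ids)) != len(tag_ids) or len(set(whale_ids)) != len(whale_ids):
            raise ValueError("tag and whale ids must be unique")

    def path(self, rel: Optional[str]) -> Optional[Path]:
        return None if rel is None else Path(self.root) / rel

    @property
    def tag_to_whale(self) -> dict[str, str]:
        return {t.tag_id: t.whale_id for t in self.tags}


def load_manifest(path) -> GroupManifest:
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    tags = [TagEntry(**entry) for entry in data["tags"]]
    period = data["analysis_period"]
    return GroupManifest(
        group_id=str(data["group_id"]),
        t_start=float(period["t_start"]),
        t_end=float(period["t_end"]),
        tags=tags,
        root=path.parent,
    )


def save_manifest(path, manifest: GroupManifest) -> None:
    data = {
        "group_id": manifest.group_id,
        "analysis_period": {"t_start": manifest.t_start, "t_end": manifest.t_end},
        "tags": [
            {k: v for k, v in vars(t).items() if v is not None} for t in manifest.tags
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
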