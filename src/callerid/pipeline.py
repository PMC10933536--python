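"""End-to-end orchestration: files in, assigned calls and summaries out.

The pipeline mirrors the analysis workflow for a simultaneously tagged
group: read per-tag selection tables (and audio / depth records), measure
received levels, cluster detections into unique calls, assign callers,
then compute call rates, silence, bout structure, exchange timing and
call-depth statistics.  Every run is deterministic given its inputs and
seed, and the run report conserves counts at each stage.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from . import acoustics, assign, dive, io, vocal
from .acoustics import RLMeasurement, TagRecording
from .assign import Detection, UniqueCall
from .simulate import Scene, SimConfig, simulate_scene
from .vocal import AnalysisPeriod

__all__ = [
    "RunConfig",
    "AlignmentError",
    "run_pipeline",
    "write_scene",
    "make_fixtures",
]

MAX_CLOCK_OFFSET_S = 60.0


class AlignmentError(ValueError):
    """A tag clock offset too large to trust the cross-tag alignment."""


@dataclass
class RunConfig:
    """Thresholds and controls for one pipeline run."""

    delta_db: float = assign.DEFAULT_DELTA_DB
    start_tolerance: float = assign.DEFAULT_START_TOLERANCE
    min_overlap_frac: float = assign.DEFAULT_MIN_OVERLAP_FRAC
    surface_threshold: float = dive.SURFACE_THRESHOLD_M
    exchange_horizon: float = 100.0
    min_icis: int = 30
    bec: Optional[float] = None  # fallback when the mixture fit is unavailable
    allow_silent_tags: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("delta_db", "start_tolerance", "min_overlap_frac",
                     "surface_threshold", "exchange_horizon"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _load_detections(manifest: io.GroupManifest, config: RunConfig, log: list[str]):
    per_tag: dict[str, list[Detection]] = {}
    dropped = 0
    for entry in manifest.tags:
        if abs(entry.clock_offset) > MAX_CLOCK_OFFSET_S:
            raise AlignmentError(
                f"{entry.tag_id}: clock offset {entry.clock_offset} s exceeds "
                f"{MAX_CLOCK_OFFSET_S} s; re-align the tag first"
            )
        if entry.selections is None:
            if entry.wav is not None and not config.allow_silent_tags:
                raise ValueError(
                    f"{entry.tag_id} has audio but no selection table "
                    "(pass allow_silent_tags to accept)"
                )
            per_tag[entry.tag_id] = []
            continue
        dets = io.read_selection_table(
            manifest.path(entry.selections), tag_id=entry.tag_id,
            clock_offset=entry.clock_offset,
        )
        kept = [d for d in dets if d.t_start >= manifest.t_start and d.t_end <= manifest.t_end]
        if len(kept) < len(dets):
            dropped += len(dets) - len(kept)
            log.append(
                f"{entry.tag_id}: dropped {len(dets) - len(kept)} detection(s) "
                "outside the analysis period"
            )
        per_tag[entry.tag_id] = kept
    return per_tag, dropped


def _measure_rls(manifest: io.GroupManifest, per_tag, log: list[str]) -> None:
    """Attach an RLMeasurement to every detection, from audio or an RL table."""
    for entry in manifest.tags:
        dets = per_tag[entry.tag_id]
        if not dets:
            continue
        if entry.wav is not None:
            fs, samples = io.read_wav(manifest.path(entry.wav))
            rec = TagRecording(
                tag_id=entry.tag_id, whale_id=entry.whale_id, fs=fs,
                samples=samples, start_time=entry.clock_offset,
                sensitivity=entry.sensitivity,
            )
            acoustics.measure_all(rec, dets)
        elif entry.rl_table is not None:
            table = pd.read_csv(manifest.path(entry.rl_table))
            lookup = {
                r["detection_id"]: (float(r["rl_db"]), bool(r["valid"]))
                for _, r in table.iterrows()
            }
            for det in dets:
                if det.detection_id in lookup:
                    rl_db, valid = lookup[det.detection_id]
                    det.rl = RLMeasurement(
                        det.detection_id, rl_db if valid else float("nan"),
                        det.t_start, det.t_end, valid,
                        None if valid else "overlap_noise",
                    )
        else:
            log.append(f"{entry.tag_id}: no audio or RL table; levels unavailable")


def _unique_call_table(calls: list[UniqueCall], tag_to_whale: dict[str, str]) -> pd.DataFrame:
    rows = []
    for uc in calls:
        tags = sorted(uc.detections)
        rls = {
            t: uc.detections[t].rl_db for t in tags if uc.detections[t].rl_db is not None
        }
        rows.append(
            {
                "call_id": uc.call_id,
                "t_start": uc.t_start,
                "n_tags": len(tags),
                "multi_tag": uc.multi_tag,
                "masked": uc.masked,
                "focal_tag": uc.focal_tag or "",
                "focal_whale": tag_to_whale.get(uc.focal_tag, "") if uc.focal_tag else "",
                "indeterminate": uc.focal_tag is None,
                "rl_difference": uc.rl_difference if uc.rl_difference is not None else float("nan"),
                "member_detections": ";".join(f"{t}={uc.detections[t].detection_id}" for t in tags),
                "member_labels": ";".join(f"{t}={uc.labels[t]}" for t in tags),
                "member_rls": ";".join(f"{t}={rls[t]:.3f}" for t in sorted(rls)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "call_id", "t_start", "n_tags", "multi_tag", "masked", "focal_tag",
            "focal_whale", "indeterminate", "rl_difference", "member_detections",
            "member_labels", "member_rls",
        ],
    )


def run_pipeline(manifest: io.GroupManifest, config: RunConfig, out_dir) -> dict:
    """Run the full analysis for one group and write all output tables.

    Returns a dict of in-memory results (DataFrames plus the fitted bout
    model and summaries); the same content is written under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    period = AnalysisPeriod(
        group_id=manifest.group_id, t_start=manifest.t_start, t_end=manifest.t_end,
        whales=tuple(t.whale_id for t in manifest.tags),
    )

    per_tag, n_dropped = _load_detections(manifest, config, log)
    _measure_rls(manifest, per_tag, log)
    all_dets = [d for dets in per_tag.values() for d in dets]

    rl_df = pd.DataFrame(
        [
            {
                "detection_id": d.detection_id,
                "tag_id": d.tag_id,
                "rl_db": d.rl.rl_db if d.rl is not None else float("nan"),
                "valid": bool(d.rl.valid) if d.rl is not None else False,
                "reason": (d.rl.invalid_reason or "") if d.rl is not None else "unmeasured",
            }
            for d in sorted(all_dets, key=lambda d: (d.tag_id, d.detection_id))
        ],
        columns=["detection_id", "tag_id", "rl_db", "valid", "reason"],
    )

    calls = assign.match_across_tags(
        all_dets, start_tolerance=config.start_tolerance,
        min_overlap_frac=config.min_overlap_frac,
    )
    for uc in calls:
        assign.assign_caller(uc, delta_db=config.delta_db)
    summary = assign.rl_difference_stats(calls)
    tag_to_whale = manifest.tag_to_whale
    uc_df = _unique_call_table(calls, tag_to_whale)

    # focal call start times per whale
    focal_times: dict[str, list[float]] = {t.whale_id: [] for t in manifest.tags}
    for uc in calls:
        if uc.focal_tag is not None:
            focal_times[tag_to_whale[uc.focal_tag]].append(
                uc.detections[uc.focal_tag].t_start
            )
    for v in focal_times.values():
        v.sort()

    prop_silent, longest_silence = vocal.silence_stats(
        [(d.t_start, d.t_end) for d in all_dets], period
    )

    pooled_icis = np.concatenate(
        [vocal.ici_series(ts) for ts in focal_times.values()]
    ) if any(len(ts) > 1 for ts in focal_times.values()) else np.empty(0)
    bout_model = None
    bec = config.bec
    try:
        bout_model = vocal.fit_bout_model(pooled_icis, min_n=config.min_icis)
        bec = bout_model.bec
    except (vocal.InsufficientDataError, vocal.DegenerateMixtureError) as exc:
        log.append(f"bout model not fitted ({exc}); "
                   + (f"using configured BEC {bec} s" if bec else "bout statistics skipped"))

    if bec is not None:
        bouts, whale_bout_df = vocal.segment_bouts(focal_times, bec, period)
    else:
        bouts, whale_bout_df = [], pd.DataFrame(
            {"whale_id": sorted(focal_times), "n_calls": [len(focal_times[w]) for w in sorted(focal_times)],
             "n_bouts": float("nan"), "bout_rate": float("nan"),
             "mean_calls_per_bout": float("nan"), "frac_in_bouts": float("nan")}
        )

    auc_kde = prop_emp = float("nan")
    try:
        cross = vocal.inter_individual_icis(focal_times)
        auc_kde, prop_emp = vocal.exchange_auc(cross, horizon=config.exchange_horizon)
        n_cross = cross.size
    except vocal.InsufficientDataError as exc:
        n_cross = 0
        log.append(f"exchange statistics skipped ({exc})")

    # depth context
    depth_series: dict[str, dive.DepthSeries] = {}
    for entry in manifest.tags:
        if entry.depth is not None:
            depth_series[entry.whale_id] = io.read_depth_csv(
                manifest.path(entry.depth), tag_id=entry.tag_id,
                clock_offset=entry.clock_offset,
            )
    call_depth_rows = []
    dives_by_whale: dict[str, list[dive.Dive]] = {}
    if depth_series:
        for whale_id, series in depth_series.items():
            dives_by_whale[whale_id] = dive.find_dives(
                series, surface_threshold=config.surface_threshold
            )
            for t in focal_times[whale_id]:
                try:
                    d = dive.depth_at(series, t)
                except dive.OutOfRangeError:
                    log.append(f"{whale_id}: call at t={t:.3f} outside depth record; excluded")
                    continue
                call_depth_rows.append({"whale_id": whale_id, "t": t, "depth_m": float(d)})
    call_depth_df = pd.DataFrame(call_depth_rows, columns=["whale_id", "t", "depth_m"])
    if len(call_depth_df):
        depth_pooled, depth_per_whale = dive.call_depth_summary(
            call_depth_df, dives_by_whale, surface_threshold=config.surface_threshold
        )
    else:
        depth_pooled, depth_per_whale = {}, pd.DataFrame()

    # per-whale summary
    whale_rows = []
    for entry in manifest.tags:
        ts = focal_times[entry.whale_id]
        row = {
            "whale_id": entry.whale_id,
            "tag_id": entry.tag_id,
            "sex": entry.sex or "",
            "age_class": entry.age_class or "",
            "n_focal": len(ts),
            "call_rate_per_h": vocal.call_rate(len(ts), period),
        }
        b = whale_bout_df[whale_bout_df["whale_id"] == entry.whale_id]
        for col in ("n_bouts", "bout_rate", "mean_calls_per_bout", "frac_in_bouts"):
            row[col] = b.iloc[0][col] if len(b) else float("nan")
        whale_rows.append(row)
    whale_df = pd.DataFrame(whale_rows)

    n_focal_total = sum(len(ts) for ts in focal_times.values())
    group_df = pd.DataFrame(
        [
            {
                "group_id": manifest.group_id,
                "duration_h": period.duration_h,
                "n_detections": len(all_dets),
                "n_unique_calls": summary.n_calls,
                "n_assigned": summary.n_assigned,
                "frac_assigned": summary.frac_assigned,
                "n_multi_tag": summary.n_multi_tag,
                "frac_multi_tag": summary.frac_multi_tag,
                "mean_rl_difference_db": summary.mean_rl_difference,
                "group_call_rate_per_h": vocal.call_rate(n_focal_total, period),
                "proportion_silent": prop_silent,
                "longest_silence_s": longest_silence,
                "bec_s": bec if bec is not None else float("nan"),
                "auc_kde": auc_kde,
                "proportion_exchange": prop_emp,
                "n_cross_intervals": n_cross,
            }
        ]
    )

    bout_df = pd.DataFrame(
        [
            {"whale_id": b.whale_id, "t_start": b.t_start, "t_end": b.t_end,
             "n_calls": b.n_calls}
            for b in bouts
        ],
        columns=["whale_id", "t_start", "t_end", "n_calls"],
    )

    report = {
        "package_version": __version__,
        "seed": config.seed,
        "group_id": manifest.group_id,
        "params": {k: v for k, v in asdict(config).items()},
        "counts": {
            "detections_in": len(all_dets) + n_dropped,
            "detections_dropped": n_dropped,
            "detections_analysed": len(all_dets),
            "detections_per_tag": {t: len(per_tag[t]) for t in sorted(per_tag)},
            "cluster_member_sum": int(sum(len(c.detections) for c in calls)),
            "unique_calls": summary.n_calls,
            "assigned": summary.n_assigned,
            "indeterminate": summary.n_indeterminate,
            "focal_detections": summary.n_focal_detections,
            "nonfocal_detections": summary.n_nonfocal_detections,
            "indeterminate_detections": summary.n_indeterminate_detections,
        },
        "log": log,
    }

    ff = "%.6f"
    rl_df.to_csv(out / "rl_measurements.csv", index=False, float_format=ff)
    uc_df.to_csv(out / "unique_calls.csv", index=False, float_format=ff)
    whale_df.to_csv(out / "whale_summary.csv", index=False, float_format=ff)
    group_df.to_csv(out / "group_summary.csv", index=False, float_format=ff)
    bout_df.to_csv(out / "bouts.csv", index=False, float_format=ff)
    call_depth_df.to_csv(out / "call_depths.csv", index=False, float_format=ff)
    if depth_per_whale is not None and len(depth_per_whale):
        depth_per_whale.to_csv(out / "call_depth_summary.csv", index=False, float_format=ff)
    dive_rows = [
        {"whale_id": w, "t_start": d.t_start, "t_end": d.t_end, "max_depth_m": d.max_depth}
        for w in sorted(dives_by_whale) for d in dives_by_whale[w]
    ]
    pd.DataFrame(dive_rows, columns=["whale_id", "t_start", "t_end", "max_depth_m"]).to_csv(
        out / "dives.csv", index=False, float_format=ff
    )
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return {
        "calls": calls,
        "unique_calls": uc_df,
        "rl_measurements": rl_df,
        "whale_summary": whale_df,
        "group_summary": group_df,
        "bouts": bout_df,
        "bout_model": bout_model,
        "call_depths": call_depth_df,
        "depth_pooled": depth_pooled,
        "assignment_summary": summary,
        "report": report,
        "focal_times": focal_times,
    }


def write_scene(scene: Scene, out_dir, waveform: Optional[bool] = None) -> Path:
    """Write a simulated scene as an analysable dataset + truth files.

    Emits one selection table and depth CSV per tag, either a WAV (waveform
    mode) or an RL table (detection-level mode) per tag, the truth tables,
    and a manifest; returns the manifest path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if waveform is None:
        waveform = scene.recordings is not None
    config = scene.config
    entries = []
    ff = "%.6f"
    for whale_id in config.whale_ids():
        tag_id = config.tag_for(whale_id)
        dets = scene.detections[tag_id]
        io.write_selection_table(out / f"{tag_id}_selections.txt", dets)
        track = scene.tracks[scene.tracks["whale_id"] == whale_id]
        io.write_depth_csv(
            out / f"{tag_id}_depth.csv",
            dive.DepthSeries(tag_id, track["t"].to_numpy(), track["depth"].to_numpy()),
        )
        entry = io.TagEntry(
            tag_id=tag_id, whale_id=whale_id,
            selections=f"{tag_id}_selections.txt",
            depth=f"{tag_id}_depth.csv",
            sensitivity=config.sensitivity,
        )
        if waveform:
            io.write_wav(out / f"{tag_id}.wav", config.fs, scene.recordings[tag_id].samples)
            entry.wav = f"{tag_id}.wav"
        else:
            pd.DataFrame(
                [
                    {"detection_id": d.detection_id, "rl_db": d.rl.rl_db, "valid": d.rl.valid}
                    for d in dets
                ],
                columns=["detection_id", "rl_db", "valid"],
            ).to_csv(out / f"{tag_id}_rl.csv", index=False, float_format=ff)
            entry.rl_table = f"{tag_id}_rl.csv"
        entries.append(entry)
    scene.calls.to_csv(out / "truth_calls.csv", index=False, float_format=ff)
    scene.rl.to_csv(out / "truth_rl.csv", index=False, float_format=ff)
    scene.links.to_csv(out / "truth_links.csv", index=False)
    scene.tracks.to_csv(out / "truth_tracks.csv", index=False, float_format="%.4f")
    manifest = io.GroupManifest(
        group_id=f"sim_seed{config.seed}",
        t_start=0.0, t_end=config.duration, tags=entries, root=out,
    )
    manifest_path = out / "manifest.yaml"
    io.save_manifest(manifest_path, manifest)
    return manifest_path


def make_fixtures(seed: int, out_dir) -> dict[str, Path]:
    """Three canonical test scenes, regenerated deterministically from a seed.

    (a) a 2-whale detection-level scene; (b) a 3-whale waveform scene in
    which at least one call reaches all three tags; (c) a two-process
    mixture ICI dataset (n=1000) for bout-criterion tests.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    cfg_a = SimConfig(n_whales=2, duration=1800.0, spacing_mean=100.0, seed=seed)
    paths["a_detection_2whale"] = write_scene(
        simulate_scene(cfg_a, waveform=False), out / "a_detection_2whale"
    )

    # sparse enough that calls rarely overlap on a tag (overlaps void the RL)
    cfg_b = SimConfig(
        n_whales=3, duration=180.0, spacing_mean=30.0, fs=24_000,
        noise_level=80.0, response_prob=0.25, bout_p=0.6,
        bout_lambda_fast=0.25, bout_lambda_slow=0.02, seed=seed + 1,
    )
    paths["b_waveform_3whale"] = write_scene(
        simulate_scene(cfg_b, waveform=True), out / "b_waveform_3whale"
    )

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))
    p, lf, ls = 0.75, 0.5, 0.01
    n = 1000
    fast = rng.random(n) < p
    icis = np.where(
        fast, rng.exponential(1.0 / lf, n), rng.exponential(1.0 / ls, n)
    )
    c_dir = out / "c_ici_mixture"
    c_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"ici_s": icis, "process": np.where(fast, "fast", "slow")}).to_csv(
        c_dir / "icis.csv", index=False, float_format="%.6f"
    )
    with open(c_dir / "truth_params.json", "w") as fh:
        json.dump({"p": p, "lambda_fast": lf, "lambda_slow": ls, "n": n}, fh, indent=2,
                  sort_keys=True)
        fh.write("\n")
    paths["c_ici_mixture"] = c_dir / "icis.csv"
    return paths
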