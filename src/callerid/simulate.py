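"""Synthetic multi-tag acoustic scenes with full ground truth.

Emulates the data-collection situation the analysis pipeline is built for:
a small group (2-3 whales) in which *every* member carries a sound-and-
movement tag, isolated from other whales.  Each whale dives in repeated
cycles, produces calls whose inter-call intervals follow a two-process
exponential mixture (fast within-bout process + slow between-bout process),
and may answer a groupmate's call after an exponential latency.  Calls
propagate to each tag with geometric spreading loss,

    RL = SL - k * log10(max(r, 1 m)),

and a detection is emitted on a tag iff the received level clears the noise
floor by the detectability SNR.  Two output fidelities share one truth
schema: detection-level (RL tables only, fast) and waveform-level (each
call rendered as a Hann-windowed FM sweep into per-tag audio plus Gaussian
background noise).
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal

from . import acoustics
from .acoustics import RLMeasurement, TagRecording
from .assign import Detection, UniqueCall

TRACK_RATE_HZ = 5.0  # matches the decimated tag sensor rate

__all__ = [
    "SimConfig",
    "Scene",
    "simulate_tracks",
    "simulate_call_times",
    "render_scene",
    "simulate_scene",
    "calibrated_call",
    "truth_accuracy",
    "InvalidConfigError",
    "AliasingError",
]


class InvalidConfigError(ValueError):
    """Simulator configuration violates an invariant."""


class AliasingError(ValueError):
    """Waveform sample rate too low for the call sweep band."""


@dataclass
class SimConfig:
    """Stated world of one synthetic deployment.

    Propagation, bout and dive parameters default to values representative
    of small groups of humpback whales on a feeding ground; the source-level
    distribution is a simulator choice (no published distribution exists for
    these social calls).
    """

    n_whales: int = 2
    duration: float = 3600.0  # s
    tag_offset: float = 1.0  # m, tag to its own whale's sound source
    spacing_mean: float = 100.0  # m, typical inter-whale distance
    spacing_model: str = "fixed"  # fixed | ou_wander
    source_level_mean: float = 150.0  # dB re 1 uPa @ 1 m
    source_level_sd: float = 6.0
    noise_level: float = 95.0  # dB re 1 uPa broadband floor
    detect_snr: float = 10.0  # dB
    spreading_coeff: float = 20.0  # k in k*log10(r)
    bout_p: float = 0.75
    bout_lambda_fast: float = 0.5  # s^-1
    bout_lambda_slow: float = 0.01  # s^-1
    response_prob: float = 0.5
    response_latency_mean: float = 20.0  # s
    call_dur_mean: float = 1.0  # s
    call_dur_sd: float = 0.3
    dive_depth_max: float = 45.0  # m
    dive_cycle_s: float = 300.0
    fs: int = 96_000  # waveform-mode sample rate
    f_low: float = 300.0  # call sweep band, Hz
    f_high: float = 800.0
    sensitivity: float = acoustics.DEFAULT_SENSITIVITY
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_whales < 1:
            raise InvalidConfigError("n_whales must be >= 1")
        if self.duration < 0:
            raise InvalidConfigError("duration must be non-negative")
        for name in ("bout_lambda_fast", "bout_lambda_slow", "dive_cycle_s", "call_dur_mean",
                     "response_latency_mean"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be positive")
        if not self.bout_lambda_fast > self.bout_lambda_slow:
            raise InvalidConfigError("bout_lambda_fast must exceed bout_lambda_slow")
        if not 0.0 < self.bout_p < 1.0:
            raise InvalidConfigError("bout_p must lie in (0, 1)")
        if not 0.0 <= self.response_prob <= 1.0:
            raise InvalidConfigError("response_prob must lie in [0, 1]")
        if self.n_whales > 1 and not self.tag_offset < self.spacing_mean:
            raise InvalidConfigError("tag_offset must be below spacing_mean")
        if self.spacing_model not in ("fixed", "ou_wander"):
            raise InvalidConfigError(f"unknown spacing_model {self.spacing_model!r}")
        if self.fs <= 0:
            raise InvalidConfigError("fs must be positive")
        if not self.f_low < self.f_high:
            raise InvalidConfigError("f_low must be below f_high")

    def whale_ids(self) -> list[str]:
        return [f"w{i}" for i in range(self.n_whales)]

    def tag_for(self, whale_id: str) -> str:
        return "tag" + whale_id[1:]


def _rng(config: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def _base_positions(config: SimConfig) -> np.ndarray:
    s = config.spacing_mean
    n = config.n_whales
    if n == 1:
        return np.zeros((1, 2))
    if n == 2:
        return np.array([[0.0, 0.0], [s, 0.0]])
    radius = s / (2.0 * np.sin(np.pi / n))
    ang = 2.0 * np.pi * np.arange(n) / n
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang)])


def _ou_offsets(rng: np.random.Generator, n: int, rate: float, sd: float,
                tau: float = 120.0) -> np.ndarray:
    dt = 1.0 / rate
    a = np.exp(-dt / tau)
    b = sd * np.sqrt(1.0 - a * a)
    z = rng.standard_normal(n)
    x = signal.lfilter([b], [1.0, -a], z)
    x[0] = sd * z[0]  # start at the stationary distribution
    return x


def _dive_profile(rng: np.random.Generator, t: np.ndarray, config: SimConfig) -> np.ndarray:
    """Repeated surface/dive cycles; smooth cosine dives, depth in [0, dive_depth_max]."""
    depth = np.zeros_like(t)
    duration = float(t[-1]) if t.size else 0.0
    cursor = 0.0
    while cursor < duration:
        surf = rng.uniform(0.15, 0.30) * config.dive_cycle_s
        dive = rng.uniform(0.60, 0.85) * config.dive_cycle_s
        dmax = rng.uniform(0.6, 1.0) * config.dive_depth_max
        d0 = cursor + surf
        d1 = d0 + dive
        sel = (t >= d0) & (t < d1)
        frac = (t[sel] - d0) / dive
        depth[sel] = dmax * 0.5 * (1.0 - np.cos(2.0 * np.pi * frac))
        cursor = d1
    return np.clip(depth, 0.0, config.dive_depth_max)


def simulate_tracks(config: SimConfig) -> pd.DataFrame:
    """Per-whale position/depth tracks at 5 Hz.

    Columns: whale_id, t, x, y, depth.  ``spacing_model='fixed'`` keeps the
    group geometry rigid at ``spacing_mean``; ``'ou_wander'`` adds
    mean-reverting (Ornstein-Uhlenbeck) horizontal wander around it.
    """
    if config.duration <= 0:
        raise InvalidConfigError("simulate_tracks requires a positive duration")
    rng = _rng(config, 0)
    n = int(round(config.duration * TRACK_RATE_HZ)) + 1
    t = np.arange(n) / TRACK_RATE_HZ
    base = _base_positions(config)
    frames = []
    for i, whale_id in enumerate(config.whale_ids()):
        x = np.full(n, base[i, 0])
        y = np.full(n, base[i, 1])
        if config.spacing_model == "ou_wander":
            sd = 0.15 * config.spacing_mean
            x = x + _ou_offsets(rng, n, TRACK_RATE_HZ, sd)
            y = y + _ou_offsets(rng, n, TRACK_RATE_HZ, sd)
        depth = _dive_profile(rng, t, config)
        frames.append(pd.DataFrame({"whale_id": whale_id, "t": t, "x": x, "y": y, "depth": depth}))
    return pd.concat(frames, ignore_index=True)


def _track_interp(tracks: pd.DataFrame, whale_id: str):
    grp = tracks[tracks["whale_id"] == whale_id]
    tt = grp["t"].to_numpy()

    def at(t):
        return np.array(
            [
                np.interp(t, tt, grp["x"].to_numpy()),
                np.interp(t, tt, grp["y"].to_numpy()),
                np.interp(t, tt, grp["depth"].to_numpy()),
            ]
        )

    return at


TRUTH_COLUMNS = ["call_id", "whale_id", "t_emit", "duration", "source_level", "emit_depth", "process"]


def simulate_call_times(config: SimConfig, tracks: Optional[pd.DataFrame]) -> pd.DataFrame:
    """Per-whale call events with ground truth.

    Each whale's base process is a renewal process whose intervals are drawn
    from ``p * Exp(lambda_fast) + (1-p) * Exp(lambda_slow)``.  On hearing a
    groupmate's base call, each other whale answers with probability
    ``response_prob`` after an Exp(response_latency_mean) latency (responses
    do not themselves trigger responses).  The ``process`` column records
    what generated each call: fast / slow (the interval that preceded it) or
    response.
    """
    rng = _rng(config, 1)
    if config.duration <= 0:
        return pd.DataFrame(columns=TRUTH_COLUMNS)
    whales = config.whale_ids()
    base: list[tuple[float, str, str]] = []
    for whale_id in whales:
        t = 0.0
        while True:
            fast = rng.random() < config.bout_p
            lam = config.bout_lambda_fast if fast else config.bout_lambda_slow
            t += rng.exponential(1.0 / lam)
            if t >= config.duration:
                break
            base.append((t, whale_id, "fast" if fast else "slow"))
    base.sort()
    responses: list[tuple[float, str, str]] = []
    if config.response_prob > 0:
        for t, caller, _ in base:
            for whale_id in whales:
                if whale_id == caller:
                    continue
                if rng.random() < config.response_prob:
                    t2 = t + rng.exponential(config.response_latency_mean)
                    if t2 < config.duration:
                        responses.append((t2, whale_id, "response"))
    events = sorted(base + responses)
    interp = {w: _track_interp(tracks, w) for w in whales} if tracks is not None else {}
    rows = []
    for k, (t, whale_id, process) in enumerate(events):
        dur = float(np.clip(rng.normal(config.call_dur_mean, config.call_dur_sd), 0.1, None))
        sl = float(rng.normal(config.source_level_mean, config.source_level_sd))
        depth = float(interp[whale_id](t)[2]) if interp else float("nan")
        rows.append(
            {
                "call_id": f"c{k:05d}",
                "whale_id": whale_id,
                "t_emit": float(t),
                "duration": dur,
                "source_level": sl,
                "emit_depth": depth,
                "process": process,
            }
        )
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def calibrated_call(
    rl_db: float,
    duration: float,
    fs: float,
    f_low: float = 300.0,
    f_high: float = 800.0,
    sensitivity: float = acoustics.DEFAULT_SENSITIVITY,
) -> np.ndarray:
    """A Hann-windowed FM sweep whose *measured* RL equals ``rl_db``.

    Calibrated against the measurement chain itself: the template is scaled
    so the rms of its conditioned (12 kHz, 500 Hz high-passed) 90% energy
    window maps to ``rl_db`` through ``sensitivity``.  A noise-free render
    therefore round-trips through :func:`callerid.acoustics.measure_rl`.
    """
    n = max(int(round(duration * fs)), 16)
    tt = np.arange(n) / fs
    template = signal.chirp(tt, f0=f_low, t1=n / fs, f1=f_high, method="linear")
    template *= signal.windows.hann(n)
    cond = acoustics.condition_array(template, fs)
    i0, i1 = acoustics.energy_window_90(cond)
    rms_unit = float(np.sqrt(np.mean(np.square(cond[i0 : i1 + 1]))))
    target_rms = 10.0 ** ((rl_db + sensitivity) / 20.0)
    return template * (target_rms / rms_unit)


@dataclass
class Scene:
    """One rendered deployment: observations plus ground truth."""

    config: SimConfig
    tracks: pd.DataFrame
    calls: pd.DataFrame  # truth: one row per emitted call
    rl: pd.DataFrame  # truth: observed RL of every call at every tag
    detections: dict[str, list[Detection]]  # tag_id -> detections
    links: pd.DataFrame  # detection_id -> call_id
    recordings: Optional[dict[str, TagRecording]] = None  # waveform mode

    @property
    def tag_to_whale(self) -> dict[str, str]:
        return {self.config.tag_for(w): w for w in self.config.whale_ids()}


def render_scene(
    config: SimConfig,
    tracks: pd.DataFrame,
    calls: pd.DataFrame,
    waveform: bool = False,
) -> Scene:
    """Propagate every call to every tag and emit detections.

    Observed RL at tag j for a call from whale i is
    ``SL - spreading_coeff * log10(max(r_ij, 1))`` with ``r_ij`` the 3-D
    source-receiver distance (``tag_offset`` on the caller's own tag).  A
    detection appears on a tag iff ``RL - noise_level >= detect_snr``.  In
    waveform mode each call is additionally rendered into per-tag audio
    (calibrated FM sweeps summed with Gaussian noise at the stated floor);
    in detection-level mode the truth RL is attached to each detection as a
    ready-made valid measurement.
    """
    whales = config.whale_ids()
    if waveform and config.fs < 2.0 * config.f_high:
        raise AliasingError(
            f"fs={config.fs} cannot represent a sweep to {config.f_high} Hz"
        )
    interp = {w: _track_interp(tracks, w) for w in whales}
    rl_rows = []
    per_tag: dict[str, list[dict]] = {config.tag_for(w): [] for w in whales}
    for call in calls.itertuples(index=False):
        pos_caller = interp[call.whale_id](call.t_emit)
        for whale_id in whales:
            tag_id = config.tag_for(whale_id)
            if whale_id == call.whale_id:
                r = config.tag_offset
            else:
                r = float(np.linalg.norm(pos_caller - interp[whale_id](call.t_emit)))
            rl = call.source_level - config.spreading_coeff * np.log10(max(r, 1.0))
            detected = (rl - config.noise_level) >= config.detect_snr
            rl_rows.append(
                {
                    "call_id": call.call_id,
                    "tag_id": tag_id,
                    "distance_m": r,
                    "rl_db": float(rl),
                    "detected": bool(detected),
                }
            )
            if detected:
                per_tag[tag_id].append(
                    {"call": call, "rl_db": float(rl), "tag_id": tag_id}
                )

    detections: dict[str, list[Detection]] = {}
    link_rows = []
    for tag_id in sorted(per_tag):
        entries = sorted(per_tag[tag_id], key=lambda e: e["call"].t_emit)
        dets = []
        for k, entry in enumerate(entries):
            call = entry["call"]
            det_id = f"{tag_id}_d{k:04d}"
            # a call starting near the end of the record is truncated with it
            t_end = min(float(call.t_emit + call.duration), config.duration)
            det = Detection(
                detection_id=det_id,
                tag_id=tag_id,
                t_start=float(call.t_emit),
                t_end=t_end,
                f_low=config.f_low,
                f_high=config.f_high,
            )
            if not waveform:
                det.rl = RLMeasurement(det_id, entry["rl_db"], det.t_start, det.t_end, True)
            dets.append(det)
            link_rows.append({"detection_id": det_id, "tag_id": tag_id, "call_id": call.call_id})
        detections[tag_id] = dets

    recordings = None
    if waveform:
        rng = _rng(config, 2)
        fs = config.fs
        nsamp = int(round(config.duration * fs))
        noise_rms = 10.0 ** ((config.noise_level + config.sensitivity) / 20.0)
        rl_lookup = {(r["call_id"], r["tag_id"]): r["rl_db"] for r in rl_rows}
        recordings = {}
        for whale_id in whales:
            tag_id = config.tag_for(whale_id)
            audio = rng.normal(0.0, noise_rms, nsamp)
            for call in calls.itertuples(index=False):
                rl = rl_lookup[(call.call_id, tag_id)]
                if rl < config.noise_level - 20.0:
                    continue  # inaudibly deep below the floor; skip the render
                wave = calibrated_call(
                    rl, call.duration, fs, config.f_low, config.f_high, config.sensitivity
                )
                i0 = int(round(call.t_emit * fs))
                i1 = min(i0 + wave.size, nsamp)
                if i0 < nsamp:
                    audio[i0:i1] += wave[: i1 - i0]
            recordings[tag_id] = TagRecording(
                tag_id=tag_id,
                whale_id=whale_id,
                fs=fs,
                samples=audio,
                start_time=0.0,
                sensitivity=config.sensitivity,
            )

    return Scene(
        config=config,
        tracks=tracks,
        calls=calls,
        rl=pd.DataFrame(rl_rows, columns=["call_id", "tag_id", "distance_m", "rl_db", "detected"]),
        detections=detections,
        links=pd.DataFrame(link_rows, columns=["detection_id", "tag_id", "call_id"]),
        recordings=recordings,
    )


def simulate_scene(config: SimConfig, waveform: bool = False) -> Scene:
    """Convenience wrapper: tracks -> call times -> rendered scene."""
    tracks = simulate_tracks(config)
    calls = simulate_call_times(config, tracks)
    return render_scene(config, tracks, calls, waveform=waveform)


def truth_accuracy(scene: Scene, assigned_calls: list[UniqueCall]) -> dict:
    """Score caller assignment against the scene's ground truth.

    A cluster is *pure* when all its member detections stem from one true
    call, and a *collision* when distinct physical calls were merged by
    temporal coincidence (a failure of span-only matching that analysts
    resolve with spectral similarity, which this model does not carry).
    ``accuracy`` scores pure clusters only - correct iff the focal tag sits
    on the true caller, with indeterminate counting as not recovered -
    while ``accuracy_all`` additionally counts every collision as wrong.
    """
    det_to_call = dict(zip(scene.links["detection_id"], scene.links["call_id"]))
    call_to_whale = dict(zip(scene.calls["call_id"], scene.calls["whale_id"]))
    tag_to_whale = scene.tag_to_whale
    n_correct = n_wrong = n_indet = n_collision = 0
    for uc in assigned_calls:
        true_calls = {det_to_call[d.detection_id] for d in uc.detections.values()}
        if len(true_calls) > 1:
            n_collision += 1
            continue
        true_whale = call_to_whale[true_calls.pop()]
        if uc.focal_tag is None:
            n_indet += 1
        elif tag_to_whale[uc.focal_tag] == true_whale:
            n_correct += 1
        else:
            n_wrong += 1
    n_pure = n_correct + n_wrong + n_indet
    total = n_pure + n_collision
    return {
        "n_clusters": total,
        "n_pure": n_pure,
        "n_collision": n_collision,
        "n_correct": n_correct,
        "n_wrong": n_wrong,
        "n_indeterminate": n_indet,
        "accuracy": n_correct / n_pure if n_pure else float("nan"),
        "accuracy_all": n_correct / total if total else float("nan"),
    }
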