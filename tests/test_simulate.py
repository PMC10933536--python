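"""Scene simulator: tracks, call processes, propagation, rendering, truth."""
import numpy as np
import pandas as pd
import pytest

from callerid import assign
from callerid.acoustics import measure_all
from callerid.simulate import (
    AliasingError,
    InvalidConfigError,
    SimConfig,
    render_scene,
    simulate_call_times,
    simulate_scene,
    simulate_tracks,
    truth_accuracy,
)


class TestConfig:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(n_whales=0),
            dict(bout_p=1.5),
            dict(bout_lambda_fast=0.01, bout_lambda_slow=0.5),
            dict(tag_offset=120.0, spacing_mean=100.0),
            dict(spacing_model="brownian"),
            dict(duration=-5.0),
            dict(f_low=900.0, f_high=800.0),
        ],
    )
    def test_invalid_configs(self, kw):
        with pytest.raises(InvalidConfigError):
            SimConfig(**kw)


class TestTracks:
    def test_depth_bounds(self):
        cfg = SimConfig(duration=1200, dive_depth_max=45.0, seed=1)
        tracks = simulate_tracks(cfg)
        assert tracks["depth"].min() >= 0.0
        assert tracks["depth"].max() <= 45.0

    def test_fixed_spacing(self):
        cfg = SimConfig(n_whales=2, duration=60, spacing_mean=100.0, seed=1)
        tr = simulate_tracks(cfg)
        a = tr[tr["whale_id"] == "w0"][["x", "y"]].to_numpy()
        b = tr[tr["whale_id"] == "w1"][["x", "y"]].to_numpy()
        assert np.allclose(np.hypot(*(a - b).T), 100.0)

    def test_ou_wander_seeding(self):
        cfg1 = SimConfig(spacing_model="ou_wander", duration=120, seed=1)
        cfg2 = SimConfig(spacing_model="ou_wander", duration=120, seed=2)
        t1, t1b = simulate_tracks(cfg1), simulate_tracks(cfg1)
        t2 = simulate_tracks(cfg2)
        pd.testing.assert_frame_equal(t1, t1b)
        assert not np.allclose(t1["x"], t2["x"])

    def test_zero_duration_rejected(self):
        with pytest.raises(InvalidConfigError):
            simulate_tracks(SimConfig(duration=0.0))


class TestCallTimes:
    def test_mixture_mean(self):
        """Sample mean ICI matches p/lf + (1-p)/ls = 26.5 s within 3 SE."""
        cfg = SimConfig(n_whales=1, duration=27_000.0, response_prob=0.0, seed=5)
        calls = simulate_call_times(cfg, None)
        icis = np.diff(calls["t_emit"].to_numpy())
        true_mean = 0.75 / 0.5 + 0.25 / 0.01
        true_var = 0.75 * 2 / 0.5**2 + 0.25 * 2 / 0.01**2 - true_mean**2
        se = np.sqrt(true_var / icis.size)
        assert abs(icis.mean() - true_mean) < 3 * se

    def test_zero_duration_empty(self):
        calls = simulate_call_times(SimConfig(duration=0.0), None)
        assert calls.empty

    def test_no_responses_when_disabled(self):
        cfg = SimConfig(duration=2000.0, response_prob=0.0, seed=5)
        calls = simulate_call_times(cfg, None)
        assert not (calls["process"] == "response").any()

    def test_responses_present_when_enabled(self):
        cfg = SimConfig(duration=2000.0, response_prob=0.8, seed=5)
        calls = simulate_call_times(cfg, None)
        assert (calls["process"] == "response").any()


def _static_scene(sl, spacing, noise_level=95.0, detect_snr=10.0):
    """One call from w0 with a rigid two-whale geometry (surfaced whales)."""
    cfg = SimConfig(
        n_whales=2, duration=10.0, spacing_mean=spacing, noise_level=noise_level,
        detect_snr=detect_snr, seed=0,
    )
    t = np.arange(0, 10.0 + 0.2, 0.2)
    tracks = pd.concat(
        [
            pd.DataFrame({"whale_id": "w0", "t": t, "x": 0.0, "y": 0.0, "depth": 0.0}),
            pd.DataFrame({"whale_id": "w1", "t": t, "x": spacing, "y": 0.0, "depth": 0.0}),
        ],
        ignore_index=True,
    )
    calls = pd.DataFrame(
        [{"call_id": "c0", "whale_id": "w0", "t_emit": 2.0, "duration": 1.0,
          "source_level": sl, "emit_depth": 0.0, "process": "fast"}]
    )
    return cfg, tracks, calls


class TestPropagation:
    def test_spreading_loss_values(self):
        """SL 155 at 1 m -> 155 dB; at 100 m with k=20 -> 115 dB."""
        cfg, tracks, calls = _static_scene(155.0, 100.0)
        scene = render_scene(cfg, tracks, calls)
        rl = scene.rl.set_index("tag_id")["rl_db"]
        assert rl["tag0"] == pytest.approx(155.0)
        assert rl["tag1"] == pytest.approx(115.0)

    def test_detectability_threshold(self):
        """RL 104 vs noise 95 gives SNR 9 < 10: no detection on that tag."""
        cfg, tracks, calls = _static_scene(144.0, 100.0)  # cross-tag RL = 104
        scene = render_scene(cfg, tracks, calls)
        det = scene.rl.set_index("tag_id")["detected"]
        assert bool(det["tag0"]) and not bool(det["tag1"])
        assert len(scene.detections["tag1"]) == 0

    def test_own_tag_always_loudest(self, detection_scene):
        """With the tag closer than any groupmate, the caller's own tag
        receives the strictly largest level for every call."""
        rl = detection_scene.rl.merge(
            detection_scene.calls[["call_id", "whale_id"]], on="call_id"
        )
        own_tag = "tag" + rl["whale_id"].str[1:]
        rl["is_own"] = rl["tag_id"] == own_tag
        for _, grp in rl.groupby("call_id"):
            own = grp.loc[grp["is_own"], "rl_db"].iloc[0]
            others = grp.loc[~grp["is_own"], "rl_db"]
            assert (own > others).all()

    def test_aliasing_guard(self):
        cfg, tracks, calls = _static_scene(150.0, 100.0)
        cfg.fs = 1000
        with pytest.raises(AliasingError):
            render_scene(cfg, tracks, calls, waveform=True)


class TestDeterminismAndTruth:
    def test_seed_reproducibility(self):
        cfg = SimConfig(n_whales=2, duration=300.0, seed=9)
        s1 = simulate_scene(cfg)
        s2 = simulate_scene(cfg)
        pd.testing.assert_frame_equal(s1.calls, s2.calls)
        pd.testing.assert_frame_equal(s1.rl, s2.rl)

    def test_waveform_reproducibility(self):
        cfg = SimConfig(n_whales=2, duration=60.0, fs=24_000, seed=9)
        s1 = simulate_scene(cfg, waveform=True)
        s2 = simulate_scene(cfg, waveform=True)
        for tag in s1.recordings:
            assert np.array_equal(s1.recordings[tag].samples, s2.recordings[tag].samples)

    def test_every_detection_links_to_one_call(self, detection_scene):
        links = detection_scene.links
        assert links["detection_id"].is_unique
        n_dets = sum(len(v) for v in detection_scene.detections.values())
        assert len(links) == n_dets

    def test_waveform_chain_assignment(self):
        """Measured RLs from rendered audio recover the true caller."""
        cfg = SimConfig(
            n_whales=2, duration=300.0, spacing_mean=100.0, fs=24_000,
            response_prob=0.0, bout_p=0.5, bout_lambda_fast=0.04,
            bout_lambda_slow=0.004, call_dur_mean=0.8, call_dur_sd=0.1, seed=3,
        )
        sc = simulate_scene(cfg, waveform=True)
        for tag, rec in sc.recordings.items():
            measure_all(rec, sc.detections[tag])
        calls = assign.match_across_tags([d for v in sc.detections.values() for d in v])
        for c in calls:
            assign.assign_caller(c)
        acc = truth_accuracy(sc, calls)
        assert acc["accuracy"] == 1.0
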