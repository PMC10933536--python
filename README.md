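# callerid

Caller identification and individual acoustic-behaviour statistics for
groups of whales that have *all* been fitted with sound-and-movement
recording tags.

## The problem

An animal-borne acoustic tag records every call that is audible at the
animal — its own and those of nearby groupmates — so a tag record alone
cannot say *who* called. Without caller identity there is no way to compute
individual call rates, silent periods, call bouts, vocal exchanges between
individuals, or the depths at which animals vocalize. When every member of
a small group (2–3 animals) carries a tag, identity can be recovered from
physics: the tag on the calling animal is closest to the sound source, so
it receives the call at the highest level regardless of the source level
the animal chose. Each call is measured on every tag and labelled

* **focal** on the tag with the clearly highest received level (RL),
* **non-focal** on the others,
* **indeterminate** when no tag stands out by at least a margin
  `delta_db` (default 3 dB).

Calls seen on only one tag are focal there; when every tag but one was
obscured by noise, the call is focal on the clean tag.

## What the package computes

* **Received levels** (`callerid.acoustics`) — rms RL in dB re 1 µPa over
  the 90% energy window of each annotated call, after decimation to 12 kHz
  and a zero-phase 500 Hz high-pass, converted through a nominal hydrophone
  sensitivity (−171 dB re 1 V/µPa).
* **Caller assignment** (`callerid.assign`) — single-linkage matching of
  near-simultaneous detections across tags into unique calls, then the
  focal/non-focal/indeterminate rules above, plus summary bookkeeping
  (assignment rate, multi-tag fraction, focal-minus-non-focal dB).
* **Vocal statistics** (`callerid.vocal`) — call rates, silence proportion
  and longest silent gap; inter-call intervals (ICIs); a maximum-likelihood
  two-process exponential mixture
  `f(t) = p·λf·exp(−λf t) + (1−p)·λs·exp(−λs t)`
  whose crossing point `BEC = ln(p·λf / ((1−p)·λs)) / (λf − λs)` is the
  bout-end criterion; bout segmentation (runs of ≥2 calls with ICIs below
  the BEC); and cross-individual exchange timing (KDE of cross-whale ICIs
  integrated over [0, 100] s).
* **Dive context** (`callerid.dive`) — depth at call time, dive
  segmentation (excursions ≥ 2 m for ≥ 10 s), per-dive maximum depths,
  surface-call fraction.
* **Scene simulator** (`callerid.simulate`) — synthetic deployments with
  whale tracks and dive cycles, bout-structured calling (two-process ICI
  mixture plus probabilistic responses to groupmates), geometric spreading
  propagation `RL = SL − k·log10(r)`, an SNR detectability rule, optional
  per-tag waveform rendering, and full ground truth for validation.
* **Pipeline and CLI** (`callerid.pipeline`, `callerid.cli`) — Raven-style
  selection tables, depth CSVs, WAV audio and a YAML group manifest in;
  unique-call, per-whale, group, bout, exchange and call-depth tables out,
  with a count-conserving run report. CLI verbs: `simulate`, `measure`,
  `assign`, `stats`, `run`, `fixtures`.

## Worked example

```python
import numpy as np
from callerid import (SimConfig, simulate_scene, match_across_tags, assign_caller,
                      rl_difference_stats, truth_accuracy, fit_bout_model, ici_series,
                      inter_individual_icis, exchange_auc, segment_bouts, AnalysisPeriod)

cfg = SimConfig(n_whales=2, duration=3600.0, spacing_mean=100.0, seed=7)
scene = simulate_scene(cfg)                      # detection-level scene + truth

detections = [d for dets in scene.detections.values() for d in dets]
calls = match_across_tags(detections)
for c in calls:
    assign_caller(c, delta_db=3.0)
summary = rl_difference_stats(calls)
print(f"{summary.n_calls} unique calls, {100*summary.frac_assigned:.0f}% assigned")
print(f"mean focal - non-focal RL difference: {summary.mean_rl_difference:.1f} dB")
print(f"truth recovery: {100*truth_accuracy(scene, calls)['accuracy']:.0f}%")

focal = {w: sorted(c.detections[c.focal_tag].t_start for c in calls
                   if c.focal_tag and scene.tag_to_whale[c.focal_tag] == w)
         for w in ("w0", "w1")}
model = fit_bout_model(np.concatenate([ici_series(ts) for ts in focal.values()]))
print(f"BEC = {model.bec:.2f} s")
bouts, per_whale = segment_bouts(focal, model.bec, AnalysisPeriod("demo", 0, cfg.duration))
auc, prop = exchange_auc(inter_individual_icis(focal), horizon=100.0)
print(f"exchange AUC over [0, 100] s: {auc:.2f}")
```

prints

```
383 unique calls, 100% assigned
mean focal - non-focal RL difference: 40.0 dB
truth recovery: 100%
BEC = 10.69 s
exchange AUC over [0, 100] s: 0.95
```

The 40 dB mean RL difference is the geometry of this scene (spacing 100 m
vs a 1 m tag offset: 20·log10(100) = 40 dB); assignment is perfect because
that gap dwarfs the 3 dB margin. The fitted BEC sits near the generator's
closed-form crossing point (10.2 s for p=0.75, λf=0.5/s, λs=0.01/s), and
the exchange AUC is the probability that a groupmate calls within 100 s.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the canonical fixture scenes from the seed, runs the full
pipeline on a detection-level and a waveform scene, scores caller-ID truth
recovery on a well-separated simulated group, and refits the two-process
bout model on a fresh mixture dataset, printing each result and writing the
JSON result file.
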