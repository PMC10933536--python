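# Methods

This note records the models, conventions and design choices behind
`callerid`, including the points where the underlying field practice leaves
the design genuinely open.

## Received-level measurement

A call annotated on a tag is measured as an rms sound pressure level:

1. the audio is decimated to 12 kHz by polyphase anti-aliased resampling
   (exact for the 64 and 96 kHz tag rates);
2. a 500 Hz high-pass strips flow noise. Only the cutoff is fixed by field
   practice; this implementation uses a 4th-order Butterworth run
   forward-backward. Zero phase avoids shifting the energy window, and the
   two passes give ~48 dB rejection at 250 Hz;
3. the 90% energy window is the span from the first sample where cumulative
   squared energy reaches 5% of the total to the first where it reaches
   95%. It is computed *after* conditioning (the alternative — windowing the
   raw segment — is equally defensible but was not chosen);
4. `RL = 20·log10(rms) − sensitivity`, with the convention that 1.0 full
   scale ≡ 1 V at the ADC and a nominal sensitivity of −171 dB re 1 V/µPa.
   The tag's true ADC gain is not modelled, so absolute levels are
   comparable within the package but carry this convention.

**Validity.** A measurement is `valid` (usable for RL statistics) only when
the call stands alone. Measurements are invalidated, with a reason, when
the annotation is noise-flagged (`overlap_noise`), overlaps another
annotation on the same tag (`overlap_call`), saturates the ADC (`clipped`,
|x| > 1 full scale), or has no energy (`silent`). Cross-tag overlap does
not invalidate: the measurement is strictly per-tag.

For `overlap_call` and `clipped` the numeric level is still recorded:

* an overlap-contaminated rms mixes two calls, but every tag sees the same
  overlapping pair, so the *ranking* across tags still identifies the
  closest tag;
* a clipped rms is a *lower bound* on the true level.

These levels feed caller assignment only (below), never the reported RL
distributions or the focal-minus-non-focal statistics.

## Caller assignment

Detections from different tags are linked when their start times differ by
≤ 0.5 s and their spans overlap by ≥ 30% of the shorter span. The 0.5 s
tolerance covers the ≤ 0.33 s acoustic travel time implied by the ≤ 500 m
group-isolation criterion plus annotation jitter. Clusters are
single-linkage connected components; because the same physical call may be
annotated with slightly different spans on each tag, single linkage is the
right closure. A cluster may never contain two detections from one tag:
links are added strongest-first (smallest start-time difference) and a link
that would merge two same-tag detections is cut. Frequency-band agreement
is deliberately not required — annotation bands are advisory.

Assignment rules, in priority order:

1. singleton cluster → focal on its tag (a call loud enough to be detected
   anywhere is always detected on its own tag under the propagation model);
2. all members but one noise-flagged → focal on the clean tag regardless of
   levels (masked-tag rule);
3. otherwise the member with the highest usable level wins iff it beats the
   runner-up by `delta_db` (default 3 dB — the field method relied on
   analyst judgement and prints no threshold; 3 dB is a factor of two in
   intensity). A clipped member may *win* (its lower bound already beats
   the rest) but a losing clipped member forces indeterminate, since its
   true level is unknown upward. Fewer than two usable levels → all
   members indeterminate.

The margin rule makes assignment conservative in exactly the situation that
defeats the physics: whales closer to each other than the RL gap can
resolve.

## Bout analysis

Within-individual inter-call intervals (start-to-start) are modelled as a
two-process exponential mixture: a fast within-bout process and a slow
between-bout process,

    f(t) = p·λf·e^(−λf·t) + (1−p)·λs·e^(−λs·t).

The fit is maximum likelihood on the **raw** intervals via EM (convergence
when the relative log-likelihood change is < 1e−8); the log transform
enters only through the initializer, a two-segment ("broken-stick")
least-squares fit to the log-frequency histogram of log intervals whose
breakpoint seeds the split into fast/slow regimes. EM for a two-exponential
mixture is monotone and order-invariant, so permuting the intervals cannot
change the estimates.

The bout-end criterion is the crossing point of the weighted component
densities,

    BEC = ln(p·λf / ((1−p)·λs)) / (λf − λs),

and a bout is a maximal run of ≥ 2 calls whose successive ICIs all fall
strictly below the BEC. Singleton calls are "not in bouts"; mean calls per
bout averages over bouts, not over calls. Degenerate fits are refused
rather than reported: a rate ratio λf/λs < 1.5, a mixture weight within
1e−4 of the boundary, or a non-positive BEC raises an error (a pure
exponential input lands here). The mixture order is fixed at two processes.

The BEC is intended to be fitted on ICIs pooled across individuals (one
criterion per dataset); per-whale fitting is available by calling
`fit_bout_model` on a single whale's series.

## Exchange timing

The cross-individual ICI attaches to each call the interval to the next
later call by any *different* individual. Its density is estimated by a
Gaussian KDE with Silverman bandwidth, reflected at zero to correct the
boundary bias of non-negative intervals, and integrated over [0, horizon]
(default 100 s) by the trapezoid rule; the empirical proportion of
intervals ≤ horizon is always reported alongside. The two agree to within
0.05 for n ≥ 500 on unimodal interval laws and on simulated group data;
a caveat: for strongly bimodal samples spanning orders of magnitude
(e.g. half the mass at ~5 s and half at ~300 s) the single Silverman
bandwidth oversmooths and the KDE integral can undershoot the empirical
proportion by ~0.1 — the empirical proportion is the robust number in that
regime.

## Dive context

Call depth is the linear interpolation of the 5 Hz depth series at the
call's start time. A dive is a maximal excursion with depth ≥ 2 m lasting
≥ 10 s: the 2 m surface threshold matches the surface-call category, and
10 s rejects pressure-sensor blips; neither constant is standardized in the
field, and both are configurable. Small negative depths (sensor noise, to
−0.5 m) are clamped to zero.

## The simulator's stated world

The generator emulates the data-collection situation the pipeline is built
for: every member of a 2–3 whale group tagged, the group isolated from
other whales. Defaults, and why:

| parameter | default | rationale |
|---|---|---|
| spacing_mean | 100 m | well-separated group; RL gap 40 dB |
| tag_offset | 1 m | tag-to-source distance on the caller's own body |
| spreading_coeff k | 20 | spherical spreading; adequate ≤ 500 m |
| source level | 150 ± 6 dB re 1 µPa @ 1 m | **config choice** — no published distribution exists for these social calls; the value sits mid-range for baleen-whale social sounds |
| noise_level | 95 dB re 1 µPa | quiet broadband feeding-ground floor |
| detect_snr | 10 dB | detectability threshold standing in for analyst detection |
| bout_p, λf, λs | 0.75, 0.5/s, 0.01/s | two-process calling with mean ICI 26.5 s and closed-form BEC 10.2 s |
| response_prob, latency | 0.5, Exp(20 s) | probabilistic answers to groupmates; the field observes exchange timing but states no mechanism, so insertion-with-latency is a modelling choice |
| call duration | 1.0 ± 0.3 s (floor 0.1 s) | typical social-call scale |
| dive_depth_max, cycle | 45 m, 300 s | feeding-ground dive depths of 30–60 m |
| sweep band | 300–800 Hz | stand-in consistent with social calls being > 100 Hz; not a realistic call synthesis |

Propagation is geometric spreading only — no absorption, multipath or
refraction — which preserves the RL ordering the method rests on at these
ranges. Tracks run at 5 Hz (the decimated tag sensor rate); dives are
smooth cosine excursions with randomized per-cycle depth and surface time,
so vertical rates stay below ~1 m/s and interpolated call depths are exact
to well under 0.2 m.

**Waveform calibration.** Each rendered call is a Hann-windowed linear FM
sweep scaled so that the rms of its *conditioned* 90% energy window equals
the target RL — i.e. calibrated against the measurement definition itself.
Scaling by the plain full-segment rms instead would miss the target by
~2–3 dB (the 90% window concentrates the Hann envelope's energy, and the
500 Hz high-pass removes part of a 300–800 Hz sweep), so the round-trip
property (render → measure within 0.5 dB) fixes the calibration choice.
Background noise is Gaussian with rms set by `noise_level` through the
same sensitivity convention.

**What a green test does and does not establish.** The simulator validates
the *machinery*: RL measurement round-trips, the propagation-driven
assignment logic, mixture recovery, interval bookkeeping, and end-to-end
determinism. It does not establish performance on real tag data: real
calls are not FM sweeps, real noise is not white, tag placement varies
(the fixed 1 m tag offset is optimistic), and real RL differences (~15 dB
in published field data) are far smaller than the 40 dB this geometry
produces. Two realistic failure modes the simulator *does* reproduce:
temporal collisions (distinct calls merged by span-only matching — scored
separately in `truth_accuracy`, because analysts resolve them with spectral
similarity that the model does not carry) and ADC clipping of very loud
calls on the caller's own tag.

## Numerical and procedural choices

* All randomness flows from a single integer seed; independent streams are
  derived per stage (tracks / calls / waveform noise) via seed sequences,
  so detection-level truth is unchanged by enabling waveform rendering.
* Output tables are written with fixed float formatting; repeated runs with
  one seed are byte-identical.
* Calls that begin near the end of a scene are truncated with the record.
* Assignment ties (equal levels) break deterministically by tag id; edge
  insertion ties in matching break by smaller start-time difference, then
  input order.
* Analysis-period bookkeeping drops detections outside the period with a
  log line; clock offsets above 60 s are refused as alignment failures.

## Known limitations

* No acoustic localization, angle-of-arrival or accelerometer-signature
  caller ID; the relative-RL method is the entire identification signal.
* Matching uses time only; two different calls starting within the
  tolerance on different tags can merge (rare at realistic call rates, and
  reported as collisions by the truth scorer).
* The KDE exchange integral is not trustworthy for extremely multi-scale
  interval distributions (use the empirical proportion).
* `dB re 1 µPa` values assume the stated full-scale-to-volts convention;
  comparing to other datasets requires knowing the true ADC gain.
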