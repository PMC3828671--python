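# Methods

This document records the models, algorithms, parameter choices and
numerical conventions implemented in `eyeblink`. Everything stated here is
either a definition or a property exercised by the test suite
(`tests/`, `scripts/acceptance.py`); no empirical claims about real animals
are made.

## 1. Conditioning paradigms and session schedules

A `ParadigmSpec` fixes stimulus geometry:

| parameter | default | meaning |
|---|---|---|
| `cs_duration_ms` | 350 | conditioned stimulus (tone) duration |
| `us_duration_ms` | 100 | unconditioned stimulus (periorbital shock) duration |
| `trace_gap_ms` | — | CS-offset-to-US-onset gap, trace paradigm only (0, 250 or 500 typical) |
| `iti_range_s` | (20, 40) | inter-trial interval range, sampled uniformly |

In the **delay** paradigm the US co-terminates with the CS, so the US onset
is `cs_duration − us_duration` = 250 ms after CS onset. In the **trace**
paradigm it is `cs_duration + trace_gap`. CS onset is placed at 300 ms into
every trace so that the full 300-ms pre-CS window exists.

Session kinds:

* **training** — 100 trials: 90 paired + 10 CS-only, with the CS-only
  trials at every tenth position (10, 20, …, 100);
* **extinction** — 100 CS-only trials;
* **spontaneous** — 100 stimulus-free trials carrying *virtual* CS/US
  timing so the identical scoring windows apply ("CR-like activity");
* **pseudo-random** — 100 CS-only and 100 US-only trials in seeded random
  order (US-only trials have no CS anchor and are excluded from scoring).

Session labels `Sp1, Sp2, T1…T8, E1…E4, R1…` sort in protocol order
(spontaneous, pseudo-random, training, extinction).

## 2. CR detection (EMG scoring)

Per session and mouse:

1. **Binning.** Each 10-kHz trace is rectified and reduced to the maximum
   absolute amplitude per 1-ms bin. Windows below are half-open in ms and
   floored to whole bins; the CS-onset bin belongs to the startle window,
   not the pre-CS window.
2. **Session threshold.** Mean + 1 sample SD (ddof = 1, configurable) of
   the pre-CS bins (300 ms × n trials) pooled over all CS-anchored trials.
3. **Validity.** The *baseline value* is the mean of pre-CS bins strictly
   exceeding the threshold (0 if none exceed); the *startle value* is the
   same over the 30 ms after CS onset. A trial is valid iff
   baseline < 10% · threshold **and** startle < 30% · threshold.
4. **CR value.** Mean of *all* bins in [US − 200 ms, US) for paired trials,
   or [expected US − 200 ms, expected US + 100 ms) for CS-only and
   stimulus-free trials.
5. **CR-positive.** A valid trial with CR value > 1% · threshold and
   > 2 × baseline value.
6. **CR%** = 100 · CR-positive / valid. With zero valid trials CR% is
   undefined: NaN plus a `cr_defined = False` flag, never 0.

All comparisons are strict. Every fraction (10%, 30%, 1%, ×2) is a
`ScoringParams` field; the 1% CR criterion is strikingly permissive but is
implemented as stated, with the default left untouched.

Numerical convention: the threshold mean/SD and all window means are
computed with `math.fsum`, which is correctly rounded and therefore
independent of accumulation order. This makes the classifier bit-identical
to any other faithful implementation of the same definitions (the test
suite verifies exact agreement with an independent straight-loop reference
on 10,000 random tiny sessions).

A structural consequence worth knowing: a trial is valid **iff no pre-CS or
startle bin exceeds the threshold** (any exceeding bin contributes itself,
and a single bin is already ≥ the threshold > the 10%/30% lines). The
validity rule is thus an artifact detector, and the threshold must sit far
above the quiescent floor for quiet trials to be valid at all — see §5.

## 3. Group statistics

* **Learning curves** — per group and session: mean CR%, SEM
  (sample SD / √n, 0 when n = 1) and n over mice; sessions with undefined
  CR% are excluded from that mouse's contribution; duplicate
  mouse × session rows are an error.
* **Mann–Whitney U** — U = #{xᵢ > yⱼ} + ½·#{xᵢ = yⱼ}. For pooled sizes
  ≤ 20 the p-value is exact: complete enumeration of all C(n, n_x)
  assignments of the pooled observations to the groups (ties handled
  naturally). One-sided p is the smaller tail; two-sided doubles it,
  capped at 1. Larger samples use the normal approximation with tie
  correction and 0.5 continuity correction.

## 4. EPSC plasticity quantification

* **QC** — a recording is discarded iff any access-resistance reading
  deviates strictly more than 20% (relative) from the *first* reading.
* **Minute averaging** — sweeps fall into minutes [60k, 60(k+1)) s anchored
  at the induction event; at the 0.1-Hz stimulation rate every full minute
  holds exactly 6 sweeps; partial minutes are flagged.
* **Normalization** — every minute mean is divided by the baseline minute
  (k = −1, the minute just before induction); the baseline maps to exactly
  1.0 and must be positive.
* **Magnitude** — 100 × mean normalized value over a window of minutes,
  default [25, 30) post-induction for LTD; the LTP readout window is a
  parameter (the conventional report time is ~35 min).

## 5. Synthetic data generator

All EMG amplitudes are in arbitrary units relative to the quiescent noise
floor `sigma_bg = 1`.

| parameter | default | why |
|---|---|---|
| `sigma_bg` | 1.0 | sets the unit; must be > 0 (degenerate thresholds are an error) |
| `tonic_fraction` | 0.05 | fraction of trials with sustained muscle tone (mouse moving); realized exactly as `round(0.05·n)` trials |
| `tonic_amplitude` | 1000 | dominates the pooled pre-CS statistics so the session threshold lands far above the quiescent floor |
| `ur_amplitude` / `ur_duration_ms` | 500 / 50 | unconditioned blink after US onset |
| `cr_amplitude` / `cr_lead_ms` | 40 / 150 | anticipatory ramp peaking at (expected) US onset |
| `slr_prob`, `slr_amplitude`, `slr_latency_ms`, `slr_duration_ms` | 0.3, 30, 5, 15 | short-latency responses within 30 ms of CS onset; land in the startle window and are small enough not to invalidate |
| `startle_prob` / `startle_amplitude` | 0.02 / 2000 | acoustic startle right after CS onset; invalidates its trial |
| `artifact_prob` / `artifact_amplitude` | 0.03 / 2000 | pre-CS movement artifact; invalidates its trial |
| learning `p0`, `p_inf`, `tau` | 0.10, 0.60 (WT) / 0.25 (mutant), 2.0 | saturating-exponential acquisition; presets land the trained CR% inside the 50–70 (WT) and 20–40 (mutant) ranges |
| `extinction_decay` | 0.4 | geometric decay from the trained level back toward `p0` |

**Why tonic trials instead of a pure Gaussian floor.** Under the scoring
definitions, validity is equivalent to "no pre-CS/startle bin above the
threshold". For pure Gaussian noise the threshold is ≈ mean + 1 SD of the
binned floor, which a single bin exceeds with probability ≈ 0.155, so the
probability that all 330 pre-CS+startle bins stay below it is ≈ 8 × 10⁻²⁵ —
*every* trial would be invalid. Conversely any threshold regime in which
quiet trials are valid makes the 1% CR line minuscule relative to the floor
mean, so *every* valid trial would be CR-positive. A realistic session must
therefore contain a minority of high-amplitude movement trials that (a)
pull the pooled threshold far above the quiescent floor and (b) are
themselves rejected. With the defaults the threshold sits near 520·σ, the
1% CR line near 5.2·σ (comfortably above the ≈ 2·σ maximum of noise-only
CR window means and below the ≈ 27·σ minimum of injected CRs), and the
tonic count is realized exactly so thresholds are comparable across mice.

Per trial, the generator samples independently: CR presence (session
probability from the learning curve), SLR, startle, pre-CS artifact, and
tonic membership; every sampled component is recorded in a ground-truth
table (`SimTruth` rows). Components are Gaussian-envelope bursts added to
the noise floor.

**What the generator emulates:** trial and session structure, acquisition /
retention / extinction dynamics at the group level, contamination and its
rejection, threshold formation, EPSC step plasticity with multiplicative
sweep noise and access-resistance drift.
**What it does not:** real EMG spectra (no motor-unit structure, no
bandpass coloration), eyelid kinematics, within-session learning, CR
latency/topography changes over training, correlated noise across trials,
electrode drift in EMG, biological variation in UR size.

**EPSC simulator.** Sweeps every 10 s from −`pre_min` to +`post_min`
minutes; amplitude `A0·(1+ε)` before induction and `A0·f·(1+ε)` after,
with `ε ~ N(0, noise_rel_sd)` per sweep (defaults `A0 = 100`,
`noise_rel_sd = 0.05`). Optional linear access-resistance drift to
`(1 + access_drift_fraction)` of the first reading exercises the QC rule.

**Determinism.** A cohort seed is expanded with
`np.random.SeedSequence(seed).spawn(n_mice)`; identical configurations
yield bit-identical archives, and the on-disk format (`%.17g` floats,
fixed column order, `float_precision="round_trip"` on read) round-trips
`float64` exactly.

## 6. Acceptance tolerances (rationale)

* **Behavioral recovery.** For 100 replicate 8-mouse cohorts at the trained
  state (T7), the detected group CR% must lie within 2 × (average per-mouse
  binomial SEM, `sqrt(p̂(1−p̂)/n_valid)`) of the programmed probability in
  ≥ 95 cohorts. The per-mouse SEM (≈ 5 points) is the natural per-animal
  sampling scale; a band of 2 × the SEM of the group estimate itself
  (≈ 1.8 points) would equal ~2σ of the very estimator being tested and
  turn the criterion into a coin flip even for a perfect detector.
* **Noisy plasticity recovery.** The magnitude estimate divides a 30-sweep
  window mean by a 6-sweep baseline mean, each with 5% per-sweep noise, so
  its SD is ≈ `100·f·0.05·sqrt(1/6 + 1/30)` ≈ `2.24·f` points. The
  ±2-point / ≥95% property is therefore testable at step fraction
  `f = 0.4` (predicted success ≈ 97.5%) and mathematically unattainable
  near `f = 1`; the noiseless-exactness property is checked at
  f ∈ {0.8, 1.0, 1.2}.

## 7. Limitations

* The scoring implements the stated definitions literally (strict
  inequalities, pooled sample SD, 1% CR line); other labs' variants (e.g.
  per-trial thresholds, population SD, onset-latency criteria) are not
  provided.
* The generator's components are additive Gaussian bursts; it validates
  pipeline correctness and statistical behavior, not biological realism,
  and its defaults were chosen from the structural analysis in §5, not
  fitted to data.
* Group comparisons are limited to the Mann–Whitney U test; repeated-
  measures designs should use external statistics tooling on the exported
  tidy tables.
* The exact Mann–Whitney enumeration is O(C(n, n_x)) and is capped at
  pooled n ≤ 20 by default.
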