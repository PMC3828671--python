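"""Synthetic conditioning experiments and EPSC series with ground truth.

The generator emulates the structure of a desk-scale eyeblink-conditioning
study: per-trial 10 kHz eyelid-EMG traces organised into daily sessions
(two spontaneous days, seven training days, optional retention and
extinction), with genotype-dependent acquisition, plus 0.1-Hz EPSC sweep
series with step-like depression or potentiation.

EMG generative model (all amplitudes in arbitrary units, relative to the
quiescent noise floor ``sigma_bg``):

* quiescent Gaussian floor, SD ``sigma_bg``, on every trial;
* a small fraction of trials (``tonic_fraction``) carry sustained
  high-amplitude muscle tone (the mouse moving in the restrainer).  These
  trials dominate the session's pooled pre-CS statistics -- they are what
  makes the session threshold (mean + 1 SD) sit far above the quiescent
  floor -- and are themselves rejected by the validity rule, exactly as
  movement-contaminated trials are in the real assay.  The tonic count is
  realized exactly (``round(fraction * n)`` trials drawn at random) so that
  session thresholds are statistically comparable across mice and sessions;
* phasic components, each a Gaussian burst with the stated envelope:
  unconditioned responses after US onset, anticipatory CR ramps peaking at
  (expected) US onset, short-latency responses within 30 ms of CS onset,
  and occasional startle or pre-CS movement artifacts large enough to
  invalidate their trial.

Acquisition follows a saturating exponential per session
``p_s = p0 + (p_inf - p0) * (1 - exp(-s / tau))``; spontaneous sessions sit
at ``p0`` and extinction decays geometrically from the trained level toward
``p0``.  Every sampled component is recorded in a per-trial ground-truth
table.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd

from .archive import DEFAULT_HEADER, EmgArchive, MANIFEST_COLUMNS
from .paradigm import (
    CS_ONSET_MS,
    ParadigmSpec,
    SessionManifest,
    build_session_manifest,
    session_kind_for_label,
    trace_duration_ms,
)
from .plasticity import EphysRecording

__all__ = [
    "LearningModel",
    "SimConfig",
    "SimulatedExperiment",
    "wt_config",
    "mutant_config",
    "session_cr_probability",
    "simulate_session",
    "simulate_mouse",
    "simulate_experiment",
    "simulate_epsc_recording",
]

TRUTH_COLUMNS = [
    "mouse_id",
    "genotype",
    "session_label",
    "trial_index",
    "trial_type",
    "cr_present",
    "slr_present",
    "startle_present",
    "artifact_present",
    "tonic_present",
    "session_cr_prob",
]

DEFAULT_SCHEDULE = ("Sp1", "Sp2", "T1", "T2", "T3", "T4", "T5", "T6", "T7")


@dataclass(frozen=True)
class LearningModel:
    """Saturating-exponential acquisition with geometric extinction.

    ``p0`` is the spontaneous CR-like rate (free simulator parameter, the
    dotted-baseline level of learning-curve figures), ``p_inf`` the
    asymptotic CR probability, ``tau`` the session time constant and
    ``extinction_decay`` the per-session geometric factor pulling the CR
    probability back toward ``p0`` during extinction.
    """

    p0: float = 0.10
    p_inf: float = 0.60
    tau: float = 2.0
    extinction_decay: float = 0.4
    n_training_sessions: int = 7

    def __post_init__(self) -> None:
        for name in ("p0", "p_inf", "extinction_decay"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.tau <= 0:
            raise ValueError("tau must be positive")

    def training_probability(self, session_number: int) -> float:
        return self.p0 + (self.p_inf - self.p0) * (
            1.0 - math.exp(-session_number / self.tau)
        )

    def extinction_probability(self, extinction_number: int) -> float:
        trained = self.training_probability(self.n_training_sessions)
        return self.p0 + (trained - self.p0) * self.extinction_decay**extinction_number


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated cohort (one genotype group)."""

    paradigm: ParadigmSpec = field(default_factory=ParadigmSpec)
    genotype: str = "wt"
    n_mice: int = 8
    schedule: tuple[str, ...] = DEFAULT_SCHEDULE
    sampling_rate_hz: float = 10000.0
    # background
    sigma_bg: float = 1.0
    tonic_fraction: float = 0.05
    tonic_amplitude: float = 1000.0
    # phasic components (amplitudes are Gaussian-burst envelope SDs, a.u.)
    ur_amplitude: float = 500.0
    ur_duration_ms: float = 50.0
    cr_amplitude: float = 40.0
    cr_lead_ms: float = 150.0
    slr_prob: float = 0.3
    slr_amplitude: float = 30.0
    slr_latency_ms: float = 5.0
    slr_duration_ms: float = 15.0
    startle_prob: float = 0.02
    startle_amplitude: float = 2000.0
    startle_duration_ms: float = 15.0
    artifact_prob: float = 0.03
    artifact_amplitude: float = 2000.0
    artifact_duration_ms: float = 10.0
    learning: LearningModel = field(default_factory=LearningModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_bg <= 0:
            raise ValueError("sigma_bg must be positive (degenerate thresholds)")
        for name in ("slr_prob", "startle_prob", "artifact_prob", "tonic_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in (
            "tonic_amplitude", "ur_amplitude", "cr_amplitude",
            "slr_amplitude", "startle_amplitude", "artifact_amplitude",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_mice < 1:
            raise ValueError("n_mice must be >= 1")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")


def wt_config(**overrides) -> SimConfig:
    """Wild-type preset: asymptotic CR% inside the 50-70 range."""
    return SimConfig(genotype="wt", **overrides)


def mutant_config(**overrides) -> SimConfig:
    """Cerebellar-mutant preset: asymptotic CR% inside the 20-40 range."""
    overrides.setdefault("learning", LearningModel(p_inf=0.25))
    return SimConfig(genotype="mutant", **overrides)


_LABEL_NUM = re.compile(r"^(Sp|T|E|R)(\d+)$")


def session_cr_probability(config: SimConfig, session_label: str) -> float:
    """True per-trial CR probability used for a session."""
    m = _LABEL_NUM.match(session_label)
    if not m:
        raise ValueError(f"unrecognized session label {session_label!r}")
    prefix, num = m.group(1), int(m.group(2))
    lm = config.learning
    if prefix in ("Sp", "R"):
        return lm.p0
    if prefix == "T":
        return lm.training_probability(num)
    return lm.extinction_probability(num)


def _ms_slice(start_ms: float, end_ms: float, rate_hz: float, n: int) -> slice:
    i0 = max(0, int(math.floor(start_ms * rate_hz / 1000.0)))
    i1 = min(n, int(math.floor(end_ms * rate_hz / 1000.0)))
    return slice(i0, max(i0, i1))


def simulate_session(
    config: SimConfig,
    manifest: SessionManifest,
    rng: np.random.Generator,
) -> tuple[np.ndarray, list[dict]]:
    """Simulate the trace matrix and truth rows for one session.

    Returns ``(traces, truth_rows)`` with ``traces`` of shape
    ``(n_trials, n_samples)`` aligned with the manifest entries.
    """
    fs = config.sampling_rate_hz
    p_cr = session_cr_probability(config, manifest.session_label)
    n_trials = len(manifest)
    n_samples = int(round(trace_duration_ms(manifest.paradigm) * fs / 1000.0))

    traces = rng.normal(0.0, config.sigma_bg, size=(n_trials, n_samples))

    n_tonic = int(round(config.tonic_fraction * n_trials))
    tonic_idx = set(
        rng.choice(n_trials, size=n_tonic, replace=False).tolist()
    ) if n_tonic else set()

    truth_rows = []
    for pos, entry in enumerate(manifest.entries):
        row = {
            "trial_index": entry.trial_index,
            "trial_type": entry.trial_type,
            "cr_present": False,
            "slr_present": False,
            "startle_present": False,
            "artifact_present": False,
            "tonic_present": pos in tonic_idx,
            "session_cr_prob": p_cr,
        }
        trace = traces[pos]
        if row["tonic_present"]:
            trace += rng.normal(0.0, config.tonic_amplitude, size=n_samples)

        cs = entry.cs_onset_ms
        us = entry.us_onset_ms
        sus = entry.scoring_us_ms  # real or expected US onset

        # unconditioned response: reflexive blink after a delivered US
        if us is not None and entry.trial_type in ("paired", "us_only"):
            sl = _ms_slice(us, us + config.ur_duration_ms, fs, n_samples)
            trace[sl] += rng.normal(0.0, config.ur_amplitude, size=sl.stop - sl.start)

        # anticipatory CR: envelope ramps linearly up to (expected) US onset
        if sus is not None and entry.trial_type in (
            "paired", "cs_only", "stimulus_free"
        ):
            if rng.uniform() < p_cr:
                row["cr_present"] = True
                sl = _ms_slice(sus - config.cr_lead_ms, sus, fs, n_samples)
                length = sl.stop - sl.start
                env = np.linspace(0.0, config.cr_amplitude, length, endpoint=False)
                trace[sl] += rng.normal(size=length) * env

        if cs is not None:
            # short-latency response within 30 ms of CS onset
            if rng.uniform() < config.slr_prob:
                row["slr_present"] = True
                sl = _ms_slice(
                    cs + config.slr_latency_ms,
                    cs + config.slr_latency_ms + config.slr_duration_ms,
                    fs, n_samples,
                )
                trace[sl] += rng.normal(
                    0.0, config.slr_amplitude, size=sl.stop - sl.start
                )
            # acoustic startle artifact (invalidates the trial)
            if rng.uniform() < config.startle_prob:
                row["startle_present"] = True
                sl = _ms_slice(
                    cs + 2.0, cs + 2.0 + config.startle_duration_ms, fs, n_samples
                )
                trace[sl] += rng.normal(
                    0.0, config.startle_amplitude, size=sl.stop - sl.start
                )
            # brief pre-CS movement artifact (invalidates the trial)
            if rng.uniform() < config.artifact_prob:
                row["artifact_present"] = True
                start = rng.uniform(
                    cs - 300.0, cs - config.artifact_duration_ms
                )
                sl = _ms_slice(
                    start, start + config.artifact_duration_ms, fs, n_samples
                )
                trace[sl] += rng.normal(
                    0.0, config.artifact_amplitude, size=sl.stop - sl.start
                )
        truth_rows.append(row)
    return traces, truth_rows


def _mouse_manifest_frame(manifests: list[SessionManifest]) -> pd.DataFrame:
    rows = []
    for man in manifests:
        for e in man.entries:
            rows.append(
                {
                    "session_label": man.session_label,
                    "trial_index": e.trial_index,
                    "trial_type": e.trial_type,
                    "cs_onset_ms": e.cs_onset_ms,
                    "us_onset_ms": e.us_onset_ms,
                    "expected_us_onset_ms": e.expected_us_onset_ms,
                    "iti_s": e.iti_s,
                }
            )
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)


def simulate_mouse(
    config: SimConfig, mouse_index: int
) -> tuple[EmgArchive, pd.DataFrame]:
    """Simulate one mouse's archive and truth table.

    Reproducible: mouse ``i`` of a config is driven by the ``i``-th spawn of
    ``SeedSequence(config.seed)``, so identical config + seed give
    byte-identical archives.
    """
    if not 0 <= mouse_index < config.n_mice:
        raise ValueError("mouse_index out of range")
    child = np.random.SeedSequence(config.seed).spawn(config.n_mice)[mouse_index]
    rng = np.random.default_rng(child)
    mouse_id = f"{config.genotype}{mouse_index + 1:02d}"

    manifests = []
    traces = {}
    truth_rows = []
    for label in config.schedule:
        kind = session_kind_for_label(label)
        man_seed = int(rng.integers(0, 2**31 - 1))
        manifest = build_session_manifest(
            config.paradigm, kind, rng_seed=man_seed, session_label=label
        )
        mat, rows = simulate_session(config, manifest, rng)
        manifests.append(manifest)
        traces[label] = mat
        for r in rows:
            r.update(
                mouse_id=mouse_id,
                genotype=config.genotype,
                session_label=label,
            )
            truth_rows.append(r)

    header = dict(DEFAULT_HEADER)
    header.update(
        {
            "mouse_id": mouse_id,
            "genotype": config.genotype,
            "sampling_rate_hz": float(config.sampling_rate_hz),
        }
    )
    archive = EmgArchive(
        header=header,
        manifest=_mouse_manifest_frame(manifests),
        traces=traces,
    )
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return archive, truth


@dataclass
class SimulatedExperiment:
    config: SimConfig
    archives: list[EmgArchive]
    truth: pd.DataFrame


def iter_mice(config: SimConfig) -> Iterator[tuple[EmgArchive, pd.DataFrame]]:
    """Yield (archive, truth) per mouse without holding the cohort in memory."""
    for i in range(config.n_mice):
        yield simulate_mouse(config, i)


def simulate_experiment(config: SimConfig) -> SimulatedExperiment:
    """Simulate the whole cohort (all mice, all scheduled sessions)."""
    archives = []
    truths = []
    for archive, truth in iter_mice(config):
        archives.append(archive)
        truths.append(truth)
    return SimulatedExperiment(
        config=config,
        archives=archives,
        truth=pd.concat(truths, ignore_index=True),
    )


def simulate_epsc_recording(
    true_fraction: float,
    noise_rel_sd: float = 0.05,
    pre_min: float = 10.0,
    post_min: float = 35.0,
    baseline_amplitude: float = 100.0,
    rate_hz: float = 0.1,
    access_resistance_mohm: float = 10.0,
    access_drift_fraction: float = 0.0,
    protocol: str = "LTD_conjunctive",
    cell_id: str = "cell",
    rng: np.random.Generator | int | None = None,
) -> EphysRecording:
    """Synthetic EPSC sweep series with a step change at induction (t = 0).

    Pre-induction sweeps have amplitude ``A0 * (1 + eps)``, post-induction
    ``A0 * true_fraction * (1 + eps)`` with ``eps ~ N(0, noise_rel_sd)``.
    Access resistance drifts linearly to ``(1 + access_drift_fraction)`` of
    its original value by the end of the recording, exercising the 20% QC
    rule when the drift exceeds it.
    """
    if true_fraction <= 0:
        raise ValueError("true_fraction must be positive")
    rng = np.random.default_rng(rng)
    dt = 1.0 / rate_hz
    n_pre = int(round(pre_min * 60.0 * rate_hz))
    n_post = int(round(post_min * 60.0 * rate_hz))
    times = (np.arange(n_pre + n_post) - n_pre) * dt
    step = np.where(times < 0, 1.0, true_fraction)
    eps = rng.normal(0.0, noise_rel_sd, size=times.size) if noise_rel_sd > 0 else 0.0
    amplitudes = np.clip(baseline_amplitude * step * (1.0 + eps), 0.0, None)
    frac = (times - times[0]) / (times[-1] - times[0])
    ar = access_resistance_mohm * (1.0 + access_drift_fraction * frac)
    return EphysRecording(
        cell_id=cell_id,
        times_s=times,
        amplitudes=amplitudes,
        access_resistance_mohm=ar,
        protocol=protocol,
        stimulation_rate_hz=rate_hz,
    )
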