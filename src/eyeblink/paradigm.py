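"""Stimulus timing for eyeblink-conditioning paradigms and session schedules.

A conditioning trial pairs a tone (conditioned stimulus, CS) with a periorbital
shock (unconditioned stimulus, US).  In the *delay* paradigm the CS precedes
and co-terminates with the US; in the *trace* paradigm a stimulus-free gap
separates CS offset from US onset.  Training sessions interleave CS-only probe
trials among paired trials; extinction sessions present the CS alone; in
spontaneous sessions nothing is presented and the trial geometry is virtual.

All times are milliseconds relative to the start of the per-trial recording
window.  Every trial with a (possibly virtual) CS places its onset at
``CS_ONSET_MS`` so that a full 300-ms pre-CS baseline window is available.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "PARADIGM_KINDS",
    "TRIAL_TYPES",
    "SESSION_KINDS",
    "CS_ONSET_MS",
    "ParadigmSpec",
    "TrialEntry",
    "SessionManifest",
    "expected_us_onset",
    "trace_duration_ms",
    "build_session_manifest",
    "session_kind_for_label",
    "session_sort_key",
]

PARADIGM_KINDS = ("delay", "trace", "pseudo_random", "spontaneous")
TRIAL_TYPES = ("paired", "cs_only", "us_only", "stimulus_free")
SESSION_KINDS = ("training", "extinction", "spontaneous", "pseudo_random")

#: CS onset within each per-trial recording window (ms).  Leaves room for the
#: 300-ms pre-CS baseline used by the scoring algorithm.
CS_ONSET_MS = 300.0

#: Minimum per-trial recording window (ms); trace-paradigm trials are extended
#: so the window covers the expected US onset plus 100 ms.
MIN_TRACE_DURATION_MS = 1000.0


@dataclass(frozen=True)
class ParadigmSpec:
    """Timing of one conditioning paradigm.

    Parameters
    ----------
    kind:
        One of ``delay``, ``trace``, ``pseudo_random``, ``spontaneous``.
    cs_duration_ms:
        Tone duration (default 350 ms).
    us_duration_ms:
        Shock duration (default 100 ms).
    trace_gap_ms:
        Stimulus-free interval between CS offset and US onset; required for
        (and only valid with) the trace paradigm.
    iti_range_s:
        Uniform range for randomized inter-trial intervals (default 20-40 s).
    """

    kind: str = "delay"
    cs_duration_ms: float = 350.0
    us_duration_ms: float = 100.0
    trace_gap_ms: float | None = None
    iti_range_s: tuple[float, float] = (20.0, 40.0)

    def __post_init__(self) -> None:
        if self.kind not in PARADIGM_KINDS:
            raise ValueError(f"unknown paradigm kind {self.kind!r}")
        if self.cs_duration_ms <= 0:
            raise ValueError("cs_duration_ms must be positive")
        if self.us_duration_ms <= 0:
            raise ValueError("us_duration_ms must be positive")
        if self.kind == "trace":
            if self.trace_gap_ms is None:
                raise ValueError("trace paradigm requires trace_gap_ms")
            if self.trace_gap_ms < 0:
                raise ValueError("trace_gap_ms must be >= 0")
        elif self.trace_gap_ms is not None:
            raise ValueError("trace_gap_ms is only defined for the trace paradigm")
        lo, hi = self.iti_range_s
        if not (0 < lo <= hi):
            raise ValueError("iti_range_s must satisfy 0 < lower <= upper")


def expected_us_onset(spec: ParadigmSpec) -> float:
    """US onset as an offset from CS onset (ms).

    Delay: the US co-terminates with the CS, so it starts at
    ``cs_duration - us_duration``.  Trace: the US starts ``trace_gap_ms``
    after CS offset.  Raises for paradigms without a deterministic offset.
    """
    if spec.kind == "delay":
        return spec.cs_duration_ms - spec.us_duration_ms
    if spec.kind == "trace":
        return spec.cs_duration_ms + float(spec.trace_gap_ms)
    raise ValueError(f"paradigm {spec.kind!r} has no deterministic US offset")


def _virtual_us_offset(spec: ParadigmSpec) -> float:
    """US offset used to anchor scoring windows, for any paradigm kind.

    Pseudo-random and spontaneous paradigms borrow the delay-style
    co-termination geometry of their CS/US durations.
    """
    if spec.kind in ("delay", "trace"):
        return expected_us_onset(spec)
    return spec.cs_duration_ms - spec.us_duration_ms


def trace_duration_ms(spec: ParadigmSpec) -> float:
    """Per-trial recording window length (ms) for this paradigm."""
    return max(
        MIN_TRACE_DURATION_MS, CS_ONSET_MS + _virtual_us_offset(spec) + 200.0
    )


@dataclass(frozen=True)
class TrialEntry:
    """One row of a session manifest.  Times are ms within the trial window;
    ``None`` encodes a field that does not apply to the trial type."""

    trial_index: int
    trial_type: str
    cs_onset_ms: float | None
    us_onset_ms: float | None
    expected_us_onset_ms: float | None
    iti_s: float

    def __post_init__(self) -> None:
        if self.trial_type not in TRIAL_TYPES:
            raise ValueError(f"unknown trial type {self.trial_type!r}")
        if self.trial_index < 1:
            raise ValueError("trial_index must be >= 1")

    @property
    def cs_anchor_ms(self) -> float | None:
        """CS onset (real or virtual) used to anchor scoring windows."""
        return self.cs_onset_ms

    @property
    def scoring_us_ms(self) -> float | None:
        """US onset (real for paired trials, expected otherwise)."""
        if self.trial_type == "paired":
            return self.us_onset_ms
        return self.expected_us_onset_ms


@dataclass(frozen=True)
class SessionManifest:
    session_label: str
    session_kind: str
    paradigm: ParadigmSpec
    entries: tuple[TrialEntry, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for i, e in enumerate(self.entries, start=1):
            if e.trial_index != i:
                raise ValueError(
                    f"trial indices must be consecutive from 1; "
                    f"entry {i} has index {e.trial_index}"
                )

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def n_paired(self) -> int:
        return sum(e.trial_type == "paired" for e in self.entries)

    @property
    def n_cs_only(self) -> int:
        return sum(e.trial_type == "cs_only" for e in self.entries)


_DEFAULT_LABELS = {
    "training": "T1",
    "extinction": "E1",
    "spontaneous": "Sp1",
    "pseudo_random": "R1",
}


def build_session_manifest(
    spec: ParadigmSpec,
    session_kind: str,
    rng_seed: int | None = None,
    session_label: str | None = None,
    n_trials: int = 100,
) -> SessionManifest:
    """Build the ordered trial schedule for one session.

    Training sessions hold 90 paired and 10 CS-only trials, the CS-only probes
    at every tenth position.  Extinction sessions are 100 CS-only trials.
    Spontaneous sessions are 100 stimulus-free trials carrying virtual CS/US
    onsets copied from the paradigm geometry.  Pseudo-random sessions
    interleave 100 CS-only and 100 US-only events in seeded random order,
    preserving per-stimulus counts while destroying the CS-US contingency.

    Inter-trial intervals are drawn uniformly from ``spec.iti_range_s`` when a
    seed is given, otherwise fixed at the range midpoint.
    """
    if session_kind not in SESSION_KINDS:
        raise ValueError(f"unknown session kind {session_kind!r}")
    if session_kind == "pseudo_random" and rng_seed is None:
        raise ValueError("pseudo_random sessions require rng_seed")
    label = session_label or _DEFAULT_LABELS[session_kind]

    cs = CS_ONSET_MS
    off = _virtual_us_offset(spec)
    us = cs + off

    if session_kind == "training":
        types = [
            "cs_only" if i % 10 == 0 else "paired" for i in range(1, n_trials + 1)
        ]
    elif session_kind == "extinction":
        types = ["cs_only"] * n_trials
    elif session_kind == "spontaneous":
        types = ["stimulus_free"] * n_trials
    else:  # pseudo_random
        types = ["cs_only"] * n_trials + ["us_only"] * n_trials

    rng = np.random.default_rng(rng_seed) if rng_seed is not None else None
    if session_kind == "pseudo_random":
        assert rng is not None
        types = [types[i] for i in rng.permutation(len(types))]

    if rng is not None:
        lo, hi = spec.iti_range_s
        itis = rng.uniform(lo, hi, size=len(types))
    else:
        itis = np.full(len(types), sum(spec.iti_range_s) / 2.0)

    entries = []
    for i, (ttype, iti) in enumerate(zip(types, itis), start=1):
        if ttype == "paired":
            entry = TrialEntry(i, ttype, cs, us, us, float(iti))
        elif ttype == "cs_only":
            entry = TrialEntry(i, ttype, cs, None, us, float(iti))
        elif ttype == "stimulus_free":
            # virtual geometry: scoring windows need anchors
            entry = TrialEntry(i, ttype, cs, None, us, float(iti))
        else:  # us_only: no CS anchor, US delivered at its usual position
            entry = TrialEntry(i, ttype, None, us, None, float(iti))
        entries.append(entry)

    return SessionManifest(label, session_kind, spec, tuple(entries))


_LABEL_KIND = {"Sp": "spontaneous", "T": "training", "E": "extinction", "R": "pseudo_random"}
_LABEL_RE = re.compile(r"^(Sp|T|E|R)(\d+)$")


def session_kind_for_label(label: str) -> str:
    """Map a conventional session label (Sp1, T3, E2, R1) to its kind."""
    m = _LABEL_RE.match(label)
    if not m:
        raise ValueError(f"unrecognized session label {label!r}")
    return _LABEL_KIND[m.group(1)]


def session_sort_key(label: str) -> tuple[int, int]:
    """Sort key giving the conventional order Sp1, Sp2, T1..T8, E1..E4."""
    m = _LABEL_RE.match(label)
    if not m:
        return (99, 0)
    order = {"Sp": 0, "R": 1, "T": 2, "E": 3}
    return (order[m.group(1)], int(m.group(2)))
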