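"""Shared fixtures and generators for the test suite.

Tiny random sessions (a few trials of a few 1-ms bins each, integer
amplitudes) are the workhorse for oracle-equivalence and invariance tests:
small enough to score by hand, rich enough to hit every branch of the
scoring rules (ties, empty exceedance sets, degenerate thresholds, mixed
trial types).
"""

from __future__ import annotations

import numpy as np
import pytest

from eyeblink.archive import TrialRecord
from eyeblink.detection import ScoringParams


def make_tiny_session(
    rng: np.random.Generator,
) -> tuple[list[TrialRecord], ScoringParams]:
    """Random tiny session: <=5 trials of <=10 one-ms bins, integer amps.

    The sampling rate is set to one sample per bin so that the per-bin
    rectified maxima equal the |trace| samples directly.
    """
    n_bins = int(rng.integers(4, 11))
    cs = int(rng.integers(2, n_bins - 1))
    pre_ms = int(rng.integers(1, cs + 1))
    startle_ms = int(rng.integers(1, n_bins - cs + 1))
    cr_post = int(rng.integers(0, min(2, n_bins - cs) + 1))
    us = int(rng.integers(cs, n_bins - cr_post + 1))
    cr_pre = int(rng.integers(1, min(us, cs) + 1))
    params = ScoringParams(
        bin_ms=1.0,
        pre_cs_window_ms=pre_ms,
        startle_window_ms=startle_ms,
        cr_window_pre_ms=cr_pre,
        cr_window_post_ms=cr_post,
    )
    n_trials = int(rng.integers(1, 6))
    trials = []
    for i in range(n_trials):
        ttype = rng.choice(["paired", "cs_only", "stimulus_free"])
        # mostly zeros with small-integer bursts: exercises ties, empty
        # exceedance sets and boundary comparisons
        amps = rng.choice([0, 0, 0, 1, 2, 3, 6], size=n_bins).astype(float)
        signs = rng.choice([-1.0, 1.0], size=n_bins)
        trials.append(
            TrialRecord(
                mouse_id="m0",
                genotype="wt",
                session_label="T1",
                trial_index=i + 1,
                trial_type=str(ttype),
                cs_onset_ms=float(cs),
                us_onset_ms=float(us) if ttype == "paired" else None,
                expected_us_onset_ms=float(us),
                iti_s=30.0,
                sampling_rate_hz=1000.0,
                trace=amps * signs,
            )
        )
    return trials, params


def tiny_session_as_reference_input(trials: list[TrialRecord]) -> list[dict]:
    """Convert tiny-session trials to the oracle's plain-dict form."""
    out = []
    for t in trials:
        out.append(
            {
                "bins": [abs(v) for v in t.trace.tolist()],
                "trial_type": t.trial_type,
                "cs_ms": t.cs_onset_ms,
                "us_ms": t.us_onset_ms,
                "eus_ms": t.expected_us_onset_ms,
            }
        )
    return out


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20231115)
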