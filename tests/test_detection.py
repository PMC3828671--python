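"""Binning, session threshold, trial scoring, and their invariants."""

import dataclasses
import math

import numpy as np
import pytest

from eyeblink.archive import TrialRecord
from eyeblink.detection import (
    BinnedTrial,
    ScoringParams,
    SessionThreshold,
    bin_max_amplitude,
    classify_session,
    compute_session_threshold,
    score_trial,
)

from .conftest import make_tiny_session, tiny_session_as_reference_input
from ._reference import reference_classify


def make_binned(amps, trial_type="paired", cs=3.0, us=None, eus=None, index=1):
    return BinnedTrial(
        amplitudes=np.asarray(amps, dtype=float),
        bin_ms=1.0,
        trial_index=index,
        trial_type=trial_type,
        cs_onset_ms=cs,
        us_onset_ms=us,
        expected_us_onset_ms=eus,
    )


class TestBinning:
    def test_constant_trace(self):
        bins = bin_max_amplitude(np.full(100, 3.0), 10000.0, 1.0)
        assert bins.shape == (10,)
        assert (bins == 3.0).all()

    def test_rectified_max(self):
        trace = np.zeros(10)
        trace[:4] = [0.1, -0.5, 0.3, 0.0]
        assert bin_max_amplitude(trace, 10000.0, 1.0)[0] == 0.5

    def test_trailing_partial_bin_dropped(self):
        bins = bin_max_amplitude(np.ones(2500), 10000.0, 1.0)
        assert bins.shape == (250,)

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            bin_max_amplitude(np.array([]), 10000.0)

    def test_bin_must_hold_a_sample(self):
        with pytest.raises(ValueError):
            bin_max_amplitude(np.ones(10), 100.0, 1.0)  # 0.1 samples/bin


class TestSessionThreshold:
    def test_zero_sd_threshold_equals_mean(self):
        trials = [make_binned([2, 2, 2, 0, 0, 0], us=6.0) for _ in range(3)]
        params = ScoringParams(pre_cs_window_ms=3, startle_window_ms=2,
                               cr_window_pre_ms=2)
        thr = compute_session_threshold(trials, params)
        assert thr.threshold == 2.0
        assert thr.sd_precs == 0.0
        assert thr.n_pooled_bins == 9

    def test_hand_computed_sample_sd(self):
        # pooled pre-CS bins {4, 6}: mean 5, sample SD sqrt(2)
        trials = [make_binned([4, 6, 0, 0, 0, 0], cs=2.0, us=6.0)]
        params = ScoringParams(pre_cs_window_ms=2, startle_window_ms=2,
                               cr_window_pre_ms=2)
        thr = compute_session_threshold(trials, params)
        assert thr.mean_precs == pytest.approx(5.0)
        assert thr.sd_precs == pytest.approx(math.sqrt(2.0))
        assert thr.threshold == pytest.approx(5.0 + math.sqrt(2.0))

    def test_deterministic(self):
        trials = [make_binned([1, 5, 2, 0, 0, 0], us=6.0)]
        params = ScoringParams(pre_cs_window_ms=3, startle_window_ms=2,
                               cr_window_pre_ms=2)
        t1 = compute_session_threshold(trials, params)
        t2 = compute_session_threshold(trials, params)
        assert t1 == t2

    def test_too_few_pooled_bins(self):
        trials = [make_binned([1, 0, 0], cs=1.0, us=3.0)]
        params = ScoringParams(pre_cs_window_ms=1, startle_window_ms=1,
                               cr_window_pre_ms=1)
        with pytest.raises(ValueError, match="pooled"):
            compute_session_threshold(trials, params)

    def test_full_default_windows_pool_300_bins_per_trial(self):
        rng = np.random.default_rng(0)
        trials = [
            make_binned(rng.uniform(0, 1, 1000), cs=300.0, us=550.0)
            for _ in range(4)
        ]
        thr = compute_session_threshold(trials, ScoringParams())
        assert thr.n_pooled_bins == 300 * 4


class TestScoreTrial:
    params = ScoringParams(pre_cs_window_ms=3, startle_window_ms=2,
                           cr_window_pre_ms=2, cr_window_post_ms=1)
    thr = SessionThreshold(mean_precs=8.0, sd_precs=2.0, threshold=10.0,
                           n_pooled_bins=100)

    def test_pre_cs_artifact_invalidates(self):
        # one pre-CS bin of 12 exceeds threshold 10 -> baseline 12 >= 1.0
        b = make_binned([12, 0, 0, 0, 0, 0, 4, 4], us=8.0)
        s = score_trial(b, self.thr, self.params)
        assert s.baseline_value == 12.0
        assert not s.is_valid
        assert not s.is_cr_positive

    def test_clean_trial_with_cr(self):
        b = make_binned([0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 4, 4], us=8.0)
        s = score_trial(b, self.thr, self.params)
        assert s.baseline_value == 0.0
        assert s.startle_value == 0.0
        assert s.is_valid
        assert s.cr_value == pytest.approx(4.0)
        assert s.is_cr_positive  # 4 > 0.1 and 4 > 0

    def test_zero_cr_window_not_positive(self):
        b = make_binned([0, 0, 0, 0, 0, 0, 0, 0], us=8.0)
        s = score_trial(b, self.thr, self.params)
        assert s.is_valid
        assert s.cr_value == 0.0
        assert not s.is_cr_positive

    def test_startle_invalidates(self):
        b = make_binned([0, 0, 0, 11, 0, 0, 4, 4], us=8.0)
        s = score_trial(b, self.thr, self.params)
        assert s.startle_value == 11.0
        assert not s.is_valid

    def test_cs_only_window_straddles_expected_us(self):
        b = make_binned([0, 0, 0, 0, 0, 6, 6, 3], trial_type="cs_only",
                        eus=7.0)
        s = score_trial(b, self.thr, self.params)
        # window [5, 8): bins 6, 6, 3
        assert s.cr_value == pytest.approx(5.0)

    def test_degenerate_threshold_rejected(self):
        bad = SessionThreshold(0.0, 0.0, 0.0, 10)
        b = make_binned([0] * 8, us=8.0)
        with pytest.raises(ValueError, match="degenerate"):
            score_trial(b, bad, self.params)

    def test_us_only_not_scoreable(self):
        b = make_binned([0] * 8, trial_type="us_only", cs=None, us=5.0)
        with pytest.raises(ValueError, match="us_only"):
            score_trial(b, self.thr, self.params)


class TestClassifySession:
    def test_cr_percent_counts(self, rng):
        # engineered session: threshold ~ tonic trials; check bookkeeping
        for _ in range(20):
            trials, params = make_tiny_session(rng)
            try:
                cls = classify_session(trials, params)
            except ValueError:
                continue
            r = cls.result
            assert 0 <= r.n_cr_positive <= r.n_valid <= r.n_trials
            if r.cr_defined:
                assert r.cr_percent == pytest.approx(
                    100.0 * r.n_cr_positive / r.n_valid
                )
                assert 0.0 <= r.cr_percent <= 100.0
            else:
                assert math.isnan(r.cr_percent)

    def test_all_contaminated_session_flags_undefined(self):
        # every trial carries a huge pre-CS artifact -> 0 valid trials
        trials = []
        for i in range(5):
            trace = np.zeros(10)
            trace[i % 3] = 1000.0
            trace[6] = 1.0
            trials.append(
                TrialRecord("m", "wt", "T1", i + 1, "paired", 3.0, 8.0, 8.0,
                            30.0, 1000.0, trace)
            )
        params = ScoringParams(pre_cs_window_ms=3, startle_window_ms=2,
                               cr_window_pre_ms=2)
        cls = classify_session(trials, params)
        assert cls.result.n_valid == 0
        assert not cls.result.cr_defined
        assert math.isnan(cls.result.cr_percent)

    def test_oracle_equivalence_small_batch(self, rng):
        """Spot check against the straight-loop transcription (the full
        10k-case sweep runs in the acceptance tests)."""
        mismatches = 0
        for _ in range(500):
            trials, params = make_tiny_session(rng)
            ref = reference_classify(
                tiny_session_as_reference_input(trials),
                pre_cs_ms=params.pre_cs_window_ms,
                startle_ms=params.startle_window_ms,
                cr_pre_ms=params.cr_window_pre_ms,
                cr_post_ms=params.cr_window_post_ms,
            )
            try:
                cls = classify_session(trials, params)
            except ValueError:
                assert ref["status"] != "ok"
                continue
            assert ref["status"] == "ok"
            assert cls.threshold.threshold == pytest.approx(
                ref["threshold"], abs=1e-12
            )
            for mine, theirs in zip(cls.scores, ref["scores"]):
                assert mine.is_valid == theirs["is_valid"]
                assert mine.is_cr_positive == theirs["is_cr_positive"]
                assert mine.baseline_value == theirs["baseline_value"]
                assert mine.cr_value == pytest.approx(theirs["cr_value"],
                                                      abs=1e-12)
        assert mismatches == 0


class TestScoringInvariants:
    def test_scale_invariance(self, rng):
        """Multiplying all traces by c > 0 preserves flags and CR%."""
        for c in (1e-3, 7.3, 1e4):
            checked = 0
            local = np.random.default_rng(7)
            while checked < 30:
                trials, params = make_tiny_session(local)
                try:
                    base = classify_session(trials, params)
                except ValueError:
                    continue
                scaled = [
                    dataclasses.replace(t, trace=t.trace * c) for t in trials
                ]
                other = classify_session(scaled, params)
                assert [s.is_valid for s in base.scores] == [
                    s.is_valid for s in other.scores
                ]
                assert [s.is_cr_positive for s in base.scores] == [
                    s.is_cr_positive for s in other.scores
                ]
                if base.result.cr_defined:
                    assert other.result.cr_percent == pytest.approx(
                        base.result.cr_percent
                    )
                checked += 1

    def test_monotonicity_in_fractions(self):
        """Looser validity fractions never lose valid trials; a stricter CR
        fraction never gains CR positives."""
        local = np.random.default_rng(11)
        checked = 0
        while checked < 40:
            trials, params = make_tiny_session(local)
            try:
                base = classify_session(trials, params)
            except ValueError:
                continue
            looser = dataclasses.replace(
                params,
                baseline_fraction=params.baseline_fraction * 3,
                startle_fraction=params.startle_fraction * 3,
            )
            stricter_cr = dataclasses.replace(params, cr_fraction=0.5)
            assert (
                classify_session(trials, looser).result.n_valid
                >= base.result.n_valid
            )
            assert (
                classify_session(trials, stricter_cr).result.n_cr_positive
                <= base.result.n_cr_positive
            )
            checked += 1
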