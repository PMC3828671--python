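"""Straight-loop reference transcription of the trial-scoring procedure.

Deliberately naive pure-Python loops, written directly from the procedure's
verbal description and kept independent of the vectorized implementation in
``eyeblink.detection`` so it can serve as an oracle: pool the pre-CS bins of
all trials, threshold = average + 1 SD; per trial, baseline/startle = average
of the bins exceeding the threshold in the pre-CS / post-CS windows (0 if
none); a trial is valid when baseline < 10% and startle < 30% of threshold;
CR value = average over the 200 ms before the US (paired) or 200 ms before
to 100 ms after the expected US (CS-only); CR-positive when the CR value
exceeds 1% of threshold and twice the baseline; CR% = CR-positive / valid.
"""

from __future__ import annotations

import math


def reference_classify(
    trials: list[dict],
    bin_ms: float = 1.0,
    pre_cs_ms: float = 300.0,
    startle_ms: float = 30.0,
    cr_pre_ms: float = 200.0,
    cr_post_ms: float = 100.0,
    baseline_fraction: float = 0.10,
    startle_fraction: float = 0.30,
    cr_fraction: float = 0.01,
    cr_multiple: float = 2.0,
    sd_ddof: int = 1,
) -> dict:
    """Score one session the slow way.

    Each trial dict needs: ``bins`` (per-bin rectified amplitudes),
    ``trial_type`` ("paired", "cs_only" or "stimulus_free"), ``cs_ms``,
    and ``us_ms`` (paired) or ``eus_ms`` (otherwise).

    Returns a dict with ``status`` ("ok", "degenerate_threshold" or
    "too_few_bins"), the threshold, per-trial scores, and session counts
    (``cr_percent`` is None when no trial is valid).
    """
    pooled = []
    for t in trials:
        lo = int(math.floor((t["cs_ms"] - pre_cs_ms) / bin_ms))
        hi = int(math.floor(t["cs_ms"] / bin_ms))
        if lo < 0 or hi > len(t["bins"]):
            raise ValueError("pre-CS window out of range")
        for k in range(lo, hi):
            pooled.append(t["bins"][k])
    if len(pooled) < 2:
        return {"status": "too_few_bins"}
    # math.fsum: correctly-rounded sums, independent of accumulation order
    mean = math.fsum(pooled) / len(pooled)
    ss = math.fsum((v - mean) ** 2 for v in pooled)
    sd = math.sqrt(ss / (len(pooled) - sd_ddof))
    threshold = mean + sd
    if threshold <= 0:
        return {"status": "degenerate_threshold", "threshold": threshold}

    scores = []
    n_valid = 0
    n_cr = 0
    for t in trials:
        bins = t["bins"]
        cs = t["cs_ms"]

        def window_avg_exceeding(start_ms, end_ms):
            lo = int(math.floor(start_ms / bin_ms))
            hi = int(math.floor(end_ms / bin_ms))
            vals = [bins[k] for k in range(lo, hi) if bins[k] > threshold]
            if not vals:
                return 0.0
            return math.fsum(vals) / len(vals)

        baseline = window_avg_exceeding(cs - pre_cs_ms, cs)
        startle = window_avg_exceeding(cs, cs + startle_ms)
        valid = (
            baseline < baseline_fraction * threshold
            and startle < startle_fraction * threshold
        )

        if t["trial_type"] == "paired":
            us = t["us_ms"]
            lo = int(math.floor((us - cr_pre_ms) / bin_ms))
            hi = int(math.floor(us / bin_ms))
        else:
            eus = t["eus_ms"]
            lo = int(math.floor((eus - cr_pre_ms) / bin_ms))
            hi = int(math.floor((eus + cr_post_ms) / bin_ms))
        vals = [bins[k] for k in range(lo, hi)]
        cr_value = math.fsum(vals) / len(vals)

        cr_positive = (
            valid
            and cr_value > cr_fraction * threshold
            and cr_value > cr_multiple * baseline
        )
        if valid:
            n_valid += 1
        if cr_positive:
            n_cr += 1
        scores.append(
            {
                "baseline_value": baseline,
                "startle_value": startle,
                "cr_value": cr_value,
                "is_valid": valid,
                "is_cr_positive": cr_positive,
            }
        )
    return {
        "status": "ok",
        "threshold": threshold,
        "scores": scores,
        "n_valid": n_valid,
        "n_cr_positive": n_cr,
        "cr_percent": (100.0 * n_cr / n_valid) if n_valid else None,
    }
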