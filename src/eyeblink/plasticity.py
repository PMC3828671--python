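"""PF-EPSC plasticity time courses: QC, minute averaging, normalization.

Parallel-fiber EPSCs are sampled at 0.1 Hz around an induction event
(conjunctive stimulation for LTD, 1-Hz tetanus for LTP).  Recordings whose
access resistance drifts by more than 20% of its original value are
discarded.  Amplitudes are averaged per minute ([60k, 60(k+1)) s relative to
induction, six sweeps per full minute at 0.1 Hz), normalized to the baseline
minute just before induction ([-60, 0) s), and the plasticity magnitude is
the mean normalized amplitude over a stated window (LTD convention:
25-30 min post-induction), expressed as percent of baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "EphysRecording",
    "QCResult",
    "PlasticityTimecourse",
    "qc_access_resistance",
    "minute_average",
    "normalize_to_baseline",
    "plasticity_magnitude",
    "analyze_recording",
    "read_sweep_table",
    "write_sweep_table",
    "group_summary",
]

SWEEP_COLUMNS = [
    "cell_id",
    "time_s",
    "epsc_amplitude",
    "access_resistance_mohm",
    "protocol",
]


@dataclass
class EphysRecording:
    """Timestamped EPSC amplitude and access-resistance series for one cell.

    Times are seconds relative to the induction event (negative = before).
    Amplitudes are magnitudes (positive, pA or arbitrary units).
    """

    cell_id: str
    times_s: np.ndarray
    amplitudes: np.ndarray
    access_resistance_mohm: np.ndarray | None = None
    protocol: str = "LTD_conjunctive"
    stimulation_rate_hz: float = 0.1

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.times_s.shape != self.amplitudes.shape:
            raise ValueError("times and amplitudes must align")
        if self.times_s.size and not np.all(np.diff(self.times_s) > 0):
            raise ValueError("sweep times must be strictly increasing")
        if np.any(self.amplitudes < 0):
            raise ValueError("EPSC amplitudes enter as magnitudes (>= 0)")
        if self.access_resistance_mohm is not None:
            self.access_resistance_mohm = np.asarray(
                self.access_resistance_mohm, dtype=float
            )


@dataclass(frozen=True)
class QCResult:
    keep: bool
    max_fractional_change: float
    first_offending_time_s: float | None


@dataclass(frozen=True)
class PlasticityTimecourse:
    cell_id: str
    minutes: pd.DataFrame  # minute, mean_amplitude, n_sweeps, is_full, normalized
    baseline_mean: float

    def magnitude(self, window: tuple[int, int] = (25, 30)) -> float:
        return plasticity_magnitude(self.minutes, window)


def qc_access_resistance(
    recording: EphysRecording,
    times_s: np.ndarray | None = None,
    max_fractional_change: float = 0.20,
) -> QCResult:
    """Discard a recording if access resistance drifts beyond tolerance.

    The "original value" is the first reading; the recording is discarded
    when any later reading deviates from it by strictly more than
    ``max_fractional_change`` (relative).
    """
    readings = recording.access_resistance_mohm
    if readings is None or readings.size == 0:
        raise ValueError("no access-resistance readings")
    r0 = float(readings[0])
    if r0 <= 0:
        raise ValueError("original access resistance must be positive")
    change = np.abs(readings - r0) / r0
    bad = np.nonzero(change > max_fractional_change)[0]
    t = recording.times_s if times_s is None else np.asarray(times_s, float)
    first_bad = None
    if bad.size:
        i = int(bad[0])
        first_bad = float(t[i]) if i < t.size else None
    return QCResult(
        keep=bad.size == 0,
        max_fractional_change=float(change.max()),
        first_offending_time_s=first_bad,
    )


def minute_average(recording: EphysRecording) -> pd.DataFrame:
    """Per-minute mean EPSC amplitudes.

    Minute ``k`` covers ``[60k, 60(k+1))`` s relative to induction; at the
    standard 0.1 Hz each full minute holds six sweeps.  Partial minutes are
    flagged via ``is_full``.  The baseline minute (k = -1) must contain at
    least one sweep.
    """
    t = recording.times_s
    if t.size == 0:
        raise ValueError("recording has no sweeps")
    minutes = np.floor(t / 60.0).astype(int)
    full_count = int(round(60.0 * recording.stimulation_rate_hz))
    rows = []
    for k in range(minutes.min(), minutes.max() + 1):
        mask = minutes == k
        n = int(mask.sum())
        rows.append(
            {
                "minute": k,
                "mean_amplitude": float(recording.amplitudes[mask].mean())
                if n
                else math.nan,
                "n_sweeps": n,
                "is_full": n == full_count,
            }
        )
    df = pd.DataFrame(rows)
    base = df[df["minute"] == -1]
    if base.empty or base.iloc[0]["n_sweeps"] == 0:
        raise ValueError("no sweeps in the baseline minute [-60, 0) s")
    return df


def normalize_to_baseline(minute_means: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Divide every minute mean by the baseline minute (k = -1) mean.

    Returns the table with a ``normalized`` column added, plus the baseline
    mean.  The baseline minute maps to exactly 1.0 by construction.
    """
    base = minute_means[minute_means["minute"] == -1]
    if base.empty:
        raise ValueError("baseline minute (-1) not present")
    baseline_mean = float(base.iloc[0]["mean_amplitude"])
    if not (baseline_mean > 0):
        raise ValueError("baseline minute mean must be positive")
    out = minute_means.copy()
    out["normalized"] = out["mean_amplitude"] / baseline_mean
    return out, baseline_mean


def plasticity_magnitude(
    normalized: pd.DataFrame, window: tuple[int, int] = (25, 30)
) -> float:
    """Mean normalized amplitude over ``[window[0], window[1])`` minutes
    post-induction, as percent of baseline."""
    lo, hi = window
    if hi <= lo:
        raise ValueError("empty magnitude window")
    wanted = set(range(lo, hi))
    sub = normalized[normalized["minute"].isin(wanted)]
    present = set(sub["minute"])
    if present != wanted:
        raise ValueError(
            f"magnitude window minutes {sorted(wanted - present)} missing "
            f"from recording"
        )
    return float(100.0 * sub["normalized"].mean())


def analyze_recording(
    recording: EphysRecording,
    window: tuple[int, int] = (25, 30),
    max_fractional_change: float = 0.20,
) -> tuple[QCResult, PlasticityTimecourse | None]:
    """QC then full time-course analysis of one cell; a discarded recording
    yields no time course."""
    qc = qc_access_resistance(recording, max_fractional_change=max_fractional_change)
    if not qc.keep:
        return qc, None
    minutes = minute_average(recording)
    minutes, baseline = normalize_to_baseline(minutes)
    return qc, PlasticityTimecourse(recording.cell_id, minutes, baseline)


def read_sweep_table(path: str | Path) -> list[EphysRecording]:
    """Read a sweep table TSV (one row per sweep) into per-cell recordings."""
    df = pd.read_csv(path, sep="\t")
    missing = set(SWEEP_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ValueError(f"sweep table missing columns {sorted(missing)}")
    recs = []
    for cell, sub in df.groupby("cell_id", sort=False):
        sub = sub.sort_values("time_s")
        ar = None
        if "access_resistance_mohm" in sub.columns and sub[
            "access_resistance_mohm"
        ].notna().any():
            ar = sub["access_resistance_mohm"].to_numpy(dtype=float)
        protocol = (
            str(sub["protocol"].iloc[0]) if "protocol" in sub.columns else "LTD_conjunctive"
        )
        recs.append(
            EphysRecording(
                cell_id=str(cell),
                times_s=sub["time_s"].to_numpy(dtype=float),
                amplitudes=sub["epsc_amplitude"].to_numpy(dtype=float),
                access_resistance_mohm=ar,
                protocol=protocol,
            )
        )
    return recs


def write_sweep_table(recordings: list[EphysRecording], path: str | Path) -> Path:
    rows = []
    for rec in recordings:
        ar = rec.access_resistance_mohm
        for i, (t, a) in enumerate(zip(rec.times_s, rec.amplitudes)):
            rows.append(
                {
                    "cell_id": rec.cell_id,
                    "time_s": t,
                    "epsc_amplitude": a,
                    "access_resistance_mohm": ar[i] if ar is not None else math.nan,
                    "protocol": rec.protocol,
                }
            )
    df = pd.DataFrame(rows, columns=SWEEP_COLUMNS)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="")
    return path


def group_summary(magnitudes: dict[str, float]) -> dict[str, float]:
    """Mean +/- SEM of windowed magnitudes across cells."""
    vals = np.array(list(magnitudes.values()), dtype=float)
    if vals.size == 0:
        raise ValueError("no cells")
    sem = float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else 0.0
    return {"mean": float(vals.mean()), "sem": sem, "n": int(vals.size)}
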