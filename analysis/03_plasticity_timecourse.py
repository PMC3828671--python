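#!/usr/bin/env python
"""Simulate an LTD experiment and quantify the plasticity time course.

Generates 10 cells with a step to 80% of baseline plus 5% sweep noise and
2 cells with a >20% access-resistance drift (which QC must discard), then
writes ``results/ltd_minute_timecourse.tsv``, ``results/ltd_cell_magnitudes.tsv``,
``results/ltd_group_summary.tsv`` and ``results/ltd_timecourse.png``.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from eyeblink.archive import write_table
from eyeblink.plasticity import analyze_recording, group_summary
from eyeblink.simulate import simulate_epsc_recording

RESULTS = Path(__file__).resolve().parents[1] / "results"
WINDOW = (25, 30)


def main() -> None:
    rng = np.random.default_rng(606)
    recordings = [
        simulate_epsc_recording(0.8, noise_rel_sd=0.05,
                                rng=int(rng.integers(2**31 - 1)),
                                cell_id=f"ltd{i:02d}")
        for i in range(10)
    ] + [
        simulate_epsc_recording(0.8, noise_rel_sd=0.05,
                                rng=int(rng.integers(2**31 - 1)),
                                access_drift_fraction=0.3,
                                cell_id=f"drift{i:02d}")
        for i in range(2)
    ]

    cell_rows, course_frames = [], []
    magnitudes: dict[str, float] = {}
    for rec in recordings:
        qc, course = analyze_recording(rec)
        row = {"cell_id": rec.cell_id, "qc_keep": qc.keep,
               "max_ar_change": qc.max_fractional_change}
        if course is not None:
            mag = course.magnitude(WINDOW)
            row["magnitude_percent"] = mag
            magnitudes[rec.cell_id] = mag
            df = course.minutes.copy()
            df.insert(0, "cell_id", rec.cell_id)
            course_frames.append(df)
        else:
            row["magnitude_percent"] = float("nan")
        cell_rows.append(row)

    RESULTS.mkdir(exist_ok=True)
    write_table(pd.DataFrame(cell_rows), RESULTS / "ltd_cell_magnitudes.tsv")
    courses = pd.concat(course_frames, ignore_index=True)
    write_table(courses, RESULTS / "ltd_minute_timecourse.tsv")
    summary = group_summary(magnitudes)
    write_table(pd.DataFrame([summary]), RESULTS / "ltd_group_summary.tsv")

    grp = courses.groupby("minute")["normalized"]
    mean, sem = grp.mean(), grp.sem()
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.errorbar(mean.index, 100 * mean, yerr=100 * sem, fmt="o", capsize=2)
    ax.axvspan(WINDOW[0], WINDOW[1], color="0.9")
    ax.axhline(100, ls=":", color="k")
    ax.set_xlabel("time from induction (min)")
    ax.set_ylabel("EPSC amplitude (% of baseline)")
    fig.tight_layout()
    fig.savefig(RESULTS / "ltd_timecourse.png", dpi=120)

    print(f"kept {len(magnitudes)}/{len(recordings)} cells; "
          f"magnitude {summary['mean']:.1f} ± {summary['sem']:.1f}% "
          f"of baseline over minutes {WINDOW[0]}-{WINDOW[1]}")


if __name__ == "__main__":
    main()
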