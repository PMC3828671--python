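#!/usr/bin/env python
"""Aggregate learning curves and compare genotypes at the end of training.

Reads ``results/session_results.tsv`` (from 01_simulate_and_score.py) and
writes ``results/group_curves.tsv``, ``results/t7_comparison.tsv`` and a
``results/learning_curves.png`` figure.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from eyeblink.archive import write_table
from eyeblink.stats import aggregate_group, exact_mann_whitney

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    results = pd.read_csv(RESULTS / "session_results.tsv", sep="\t")
    curves = aggregate_group(results)
    write_table(curves, RESULTS / "group_curves.tsv")

    t7 = results[results["session_label"] == "T7"]
    wt = t7.loc[t7["group"] == "wt", "cr_percent"].to_numpy()
    mut = t7.loc[t7["group"] == "mutant", "cr_percent"].to_numpy()
    mwu = exact_mann_whitney(wt, mut)
    write_table(pd.DataFrame([{
        "session_label": "T7",
        "u_statistic": mwu.u_statistic,
        "p_two_sided": mwu.p_two_sided,
        "n_wt": mwu.n_x,
        "n_mutant": mwu.n_y,
        "method": mwu.method,
    }]), RESULTS / "t7_comparison.tsv")

    fig, ax = plt.subplots(figsize=(6, 4))
    for group, sub in curves.groupby("group"):
        ax.errorbar(range(len(sub)), sub["mean_cr_percent"], yerr=sub["sem"],
                    marker="o", capsize=3, label=group)
        ax.set_xticks(range(len(sub)))
        ax.set_xticklabels(sub["session_label"], rotation=45)
    ax.set_xlabel("session")
    ax.set_ylabel("CR%  (mean ± SEM)")
    ax.set_ylim(0, 100)
    ax.legend()
    fig.tight_layout()
    fig.savefig(RESULTS / "learning_curves.png", dpi=120)

    print(curves.to_string(index=False))
    print(f"\nT7 wt vs mutant: U = {mwu.u_statistic}, "
          f"two-sided p = {mwu.p_two_sided:.4g} ({mwu.method})")


if __name__ == "__main__":
    main()
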