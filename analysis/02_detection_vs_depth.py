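#!/usr/bin/env python
"""Detected transcripts per cell versus sequencing depth.

Recomputes the per-cell detection summary of the simulated cohort, the
Pearson correlation between transcripts detected and total reads, and the
decline of detected transcripts along the differentiation branch — the
depth diagnostics used to argue that lower transcript detection in
differentiating cells is biology, not data acquisition.
"""

from pathlib import Path

from scipy.stats import spearmanr

from scwaterfall import (
    detection_decline_along_branch,
    detection_depth_correlation,
    detection_summary,
    read_counts,
)

DATA = Path("results/data")
OUT = Path("results/analysis")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    m = read_counts(DATA / "counts.tsv", "dense-table")
    det = detection_summary(m, threshold=1)
    det.to_frame().to_csv(OUT / "detection_summary.tsv", sep="\t")
    gates = m.gates()
    x1 = det.per_cell_detected[gates == "X1"].mean()
    x2 = det.per_cell_detected[gates == "X2"].mean()
    r = detection_depth_correlation(det)
    print(f"mean detected transcripts: X1 {x1:.0f}, X2 {x2:.0f}")
    print(f"detection vs depth Pearson r = {r:.4f}")

    decline = detection_decline_along_branch(seed=7)
    decline.to_csv(OUT / "detection_along_differentiation.tsv", sep="\t",
                   index=False, float_format="%.10g")
    rho = spearmanr(decline["t"], decline["mean_detected"]).statistic
    print(
        "detected transcripts along the differentiation branch: "
        f"rank correlation with pseudotime = {rho:.3f} "
        "(declines as cells leave the stem compartment)"
    )


if __name__ == "__main__":
    main()
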