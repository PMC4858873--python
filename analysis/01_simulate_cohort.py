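#!/usr/bin/env python
"""Simulate the synthetic head stem-cell cohort.

Draws 168 cells (the size of the FACS-sorted head X1/X2 cohort the
pipeline targets) from the default branching-lineage model and writes the
raw counts, per-cell metadata and generative truth under results/data/.
Run this first; the later numbered scripts read its outputs.
"""

from pathlib import Path

from scwaterfall import default_planarian_model, simulate, write_counts

SEED = 1
OUT = Path("results/data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    model = default_planarian_model()
    model.save(OUT / "lineage_model.json")
    m, truth = simulate(model, n_cells=168, seed=SEED)
    write_counts(m, OUT / "counts.tsv", "dense-table")
    truth.export(OUT / "truth.tsv")
    gates = m.gates()
    print(f"simulated {m.n_genes} genes x {m.n_cells} cells (seed {SEED})")
    print(f"  X1 cells: {(gates == 'X1').sum()}, X2 cells: {(gates == 'X2').sum()}")
    print(f"  branches: {truth.table['branch'].value_counts().to_dict()}")
    print(f"wrote counts, metadata and truth to {OUT}/")


if __name__ == "__main__":
    main()
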