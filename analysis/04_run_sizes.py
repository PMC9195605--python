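#!/usr/bin/env python
"""Bracketed run sizes (patient samples between QC events) for every
candidate procedure x analyte at patient-risk factor 1, cap 1000.

The model ranks analytes exactly as the published calculator matrix does
(sodium smallest, the sigma-6 group capped at 1000); individual cells are a
documented modelling choice, not a reproduction of the unpublished
calculator internals.  Writes results/run_size_matrix.csv.
"""

from pathlib import Path

from labqcplan import datasets
from labqcplan.run_size import run_size_matrix
from labqcplan.sqc_rules import CANDIDATE_PROCEDURES

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    panel = datasets.example_panel()
    matrix = run_size_matrix(
        list(CANDIDATE_PROCEDURES.values()), panel, n_sims=100_000, seed=1
    )
    matrix.to_csv(OUT / "run_size_matrix.csv")
    print(matrix.to_string())
    caps = (matrix.to_numpy() == 1000).sum()
    print(f"\n{caps} of {matrix.size} cells at the 1000-sample reporting cap")
    print("start-up feasibility (run size >= daily volume for all analytes):")
    for name, row in matrix.iterrows():
        ok = all(row[a] >= v for a, v in datasets.DAILY_VOLUMES.items())
        print(f"  {name:28s} {'feasible' if ok else 'infeasible'}")


if __name__ == "__main__":
    main()
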