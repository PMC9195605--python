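#!/usr/bin/env python
"""Assemble the multistage risk-based QC plan for the 10-analyte panel.

Start-up and monitor SQC procedures are selected panel-wide from the
published run-size matrix; the MA role per analyte comes from the published
TEa-bias detection summaries.  Writes results/qc_plan.json and
results/qc_plan.md.
"""

import json
from dataclasses import asdict
from pathlib import Path

import labqcplan as lq
from labqcplan import datasets
from labqcplan.plan_builder import plan_to_markdown

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    entries, frame = lq.build_plan(
        datasets.example_panel(),
        datasets.published_run_size_matrix(),
        datasets.published_ma_summaries(),
        list(lq.CANDIDATE_PROCEDURES.values()),
    )
    payload = [
        {**asdict(e), "category": e.category.label} for e in entries
    ]
    (OUT / "qc_plan.json").write_text(json.dumps(payload, indent=2) + "\n")
    (OUT / "qc_plan.md").write_text(plan_to_markdown(entries) + "\n")

    print(frame[["analyte", "category", "startup", "monitor"]].to_string(index=False))
    n_ma = sum(e.monitor_procedure == "MA" for e in entries)
    print(f"\n{n_ma} of {len(entries)} analytes monitored by MA alone;")
    print(f"{len(entries) - n_ma} keep the SQC monitor with MA as supplement.")


if __name__ == "__main__":
    main()
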