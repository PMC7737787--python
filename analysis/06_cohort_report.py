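#!/usr/bin/env python
"""Tabulate the cohort summary: class counts per sample, per-patient cycle
and partial-EMT proportions (with numerators/denominators), marker-positive
fractions and CTA burden quartiles.

Every percentage is emitted alongside its integer numerator and denominator
and is recomputable with report_proportion.  Writes cohort_summary.json and
cohort_per_sample.tsv.
"""

import json
from pathlib import Path

import pandas as pd

from csfctc.io import load_counts
from csfctc.qc import compute_qc, run_qc
from csfctc.report import summarize_cohort

ROOT = Path(__file__).resolve().parents[1] / "results"

cm = load_counts(ROOT / "cohort" / "counts")
cm_qc, _ = run_qc(cm)
ann = pd.read_csv(ROOT / "cell_annotations.tsv", sep="\t", index_col=0)
qc = compute_qc(cm_qc)

summary = summarize_cohort(
    ann, qc.per_cell, cm_qc.cell_meta["sample_id"], cm_qc.cell_meta["patient_id"]
)
summary.per_sample.to_csv(ROOT / "cohort_per_sample.tsv", sep="\t")
(ROOT / "cohort_summary.json").write_text(
    json.dumps(
        {"per_patient": summary.per_patient, "across_patient_means": summary.across_patient_means},
        indent=2,
    )
)

print("per-sample class counts:")
print(summary.per_sample)
for pid, entry in summary.per_patient.items():
    cyc = entry.get("cycling", {})
    print(f"{pid}: cycling {cyc.get('percent')}% "
          f"({cyc.get('numerator')}/{cyc.get('denominator')})")
print(f"across-patient mean cycling: {summary.across_patient_means.get('cycling')}%")
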