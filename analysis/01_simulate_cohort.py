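#!/usr/bin/env python
"""Generate the five-patient synthetic CSF cohort used by every later step.

Writes the count matrix (MTX + sidecars + metadata) and the planted ground
truth to results/cohort/.  The cohort emulates FACS-sorted Smart-seq2 CSF
cells: a CTC majority with minority T/B/monocyte populations, patient-private
tumor programs, a ~10% cycling subpopulation, ~30% partial-EMT CTCs, and
sparse cancer-testis antigen detections.
"""

from pathlib import Path

from csfctc.io import write_counts
from csfctc.synthdata import make_fixture

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"

cm, truth = make_fixture("cohort")
write_counts(cm, OUT / "counts", format="mtx")
truth.cells.to_csv(OUT / "truth_cells.tsv", sep="\t")
truth.genes.to_csv(OUT / "truth_genes.tsv", sep="\t")

pops = truth.cells["population"].value_counts().to_dict()
print(f"wrote {cm.n_genes} genes x {cm.n_cells} cells for "
      f"{truth.cells['patient'].nunique()} patients -> {OUT}")
print(f"planted composition: {pops}")
ctc_cycling = truth.cells.loc[truth.cells["population"] == "CTC", "cycling"].mean()
print(f"planted cycling CTC fraction: {ctc_cycling:.3f}")
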