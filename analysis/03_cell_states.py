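#!/usr/bin/env python
"""Score cell states: cycle phase, partial EMT, stemness flags, CTA burden.

Cycle calls use G1/S / G2/M module scores with the 0.2 / 0 thresholds
(cycling / intermediate / non-cycling).  Partial EMT requires both the
epithelial and mesenchymal/CSC set-variation scores to exceed 0.5.
Stemness flags and per-cell CTA burden use detectable expression.
Appends all state columns to results/cell_annotations.tsv.
"""

from pathlib import Path

import pandas as pd

from csfctc import datasets, normalize
from csfctc.classify import (
    assign_cycle_states,
    classify_partial_emt,
    csc_positivity,
    cta_burden,
)
from csfctc.io import load_counts
from csfctc.qc import run_qc
from csfctc.scoring import cycle_scores, gsva_like_score

ROOT = Path(__file__).resolve().parents[1] / "results"

cm = load_counts(ROOT / "cohort" / "counts")
truth = pd.read_csv(ROOT / "cohort" / "truth_cells.tsv", sep="\t", index_col=0)
cm_qc, _ = run_qc(cm)
em = normalize(cm_qc)
ann = pd.read_csv(ROOT / "cell_annotations.tsv", sep="\t", index_col=0)

g1s_genes, g2m_genes = datasets.cell_cycle_sets()
g1s, g2m = cycle_scores(em, g1s_genes, g2m_genes, seed=0)
ann["g1s_score"], ann["g2m_score"] = g1s, g2m
ann["cycle_state"] = assign_cycle_states(g1s, g2m)

emt = gsva_like_score(em, datasets.emt_sets())
ann["epi_score"] = emt.scores.loc["epithelial7"].to_numpy()
ann["mes_csc_score"] = emt.scores.loc["mes_csc"].to_numpy()
ann["ecm_score"] = emt.scores.loc["ecm"].to_numpy()
ann["partial_emt"] = classify_partial_emt(ann["epi_score"], ann["mes_csc_score"])

flags = csc_positivity(cm_qc.counts, cm_qc.gene_ids, cm_qc.cell_ids)
ann = ann.join(flags)
ann["cta_count"] = cta_burden(cm_qc.counts, cm_qc.gene_ids, datasets.cta_list())
ann.to_csv(ROOT / "cell_annotations.tsv", sep="\t")

t = truth.loc[ann.index]
ctc = ann["cell_type"] == "CTC"
rec = (ann.loc[ctc, "cycle_state"] == "cycling").mean()
planted = t.loc[ctc.to_numpy(), "cycling"].mean()
print(f"cycling CTC fraction: recovered {rec:.1%} vs planted {planted:.1%}")
print(f"partial-EMT CTC fraction: recovered {ann.loc[ctc, 'partial_emt'].mean():.1%} "
      f"vs planted {t.loc[ctc.to_numpy(), 'partial_emt'].mean():.1%}")
print(f"mean CTA burden per CTC: {ann.loc[ctc, 'cta_count'].mean():.2f}")
print(f"CD44+ CTCs: {ann.loc[ctc, 'CD44_pos'].mean():.1%}; "
      f"CD44+ALDH1A1+ dual: {ann.loc[ctc, 'CD44_ALDH1A1_dual'].sum()} cells")
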