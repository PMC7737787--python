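#!/usr/bin/env python
"""Differential expression: CTC-vs-immune signature, per-patient signatures,
and a diagnostic gene panel.

CTC-vs-immune uses the rank-sum test with BH adjustment (adjusted p < .05,
|log2FC| > 1).  Per-patient one-vs-rest signatures use the more permissive
raw p < .05 with fold change > 1.5.  The diagnostic panel keeps genes highly
detected in CTCs and nearly absent in immune cells, ranked by detection gap.
Writes de_ctc_vs_immune.tsv, patient_signatures.tsv and panel.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from csfctc.diffexpr import PanelCriteria, de_two_group, patient_signatures, select_panel
from csfctc.io import load_counts
from csfctc.qc import run_qc

ROOT = Path(__file__).resolve().parents[1] / "results"

cm = load_counts(ROOT / "cohort" / "counts")
cm_qc, _ = run_qc(cm)
ann = pd.read_csv(ROOT / "cell_annotations.tsv", sep="\t", index_col=0)
ctc = list(ann.index[ann["cell_type"] == "CTC"])
immune = list(ann.index[ann["cell_type"].isin(["T", "B", "monocyte"])])

de = de_two_group(cm_qc, ctc, immune)
de["neg_log10_p_adj"] = -np.log10(de["p_adj"])
de.to_csv(ROOT / "de_ctc_vs_immune.tsv", sep="\t")
n_up = int(((de["p_adj"] < 0.05) & (de["log2_fc"] > 1)).sum())
print(f"{n_up} genes up in CTCs at adjusted p < .05 and log2FC > 1")
top = de[(de["p_adj"] < 0.05)].nlargest(5, "log2_fc")
print("top CTC genes by fold change:")
print(top[["log2_fc", "p_adj", "detect_frac_a", "detect_frac_b"]].round(3))

sigs = patient_signatures(cm_qc, cm_qc.cell_meta["patient_id"])
rows = [{"patient": p, "n_genes": len(g), "genes": ",".join(g)} for p, g in sigs.items()]
pd.DataFrame(rows).to_csv(ROOT / "patient_signatures.tsv", sep="\t", index=False)
print("patient signature sizes:", {p: len(g) for p, g in sigs.items()})

panel = select_panel(de, PanelCriteria())
panel.to_csv(ROOT / "panel.tsv", sep="\t")
print(f"diagnostic panel ({len(panel)} genes):", ", ".join(panel.index[:10]),
      "..." if len(panel) > 10 else "")
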