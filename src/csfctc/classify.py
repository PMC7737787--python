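"""Per-cell identity and state calls.

Cell typing replaces heatmap inspection with an explicit, configurable
positivity rule: a marker panel is positive in a cell when at least
``min_detected`` of its genes are detected (raw count > 0, equivalently
log-normalized value > 0) or its module score exceeds ``score_threshold``.
A cell is immune if the leukocyte panel or any immune panel (T, B,
monocyte) is positive — immune positivity takes priority over tumor
panels — and is then typed by its highest-scoring immune panel.  Otherwise
the cell is a CTC if the epithelial or lung-origin panel is positive, else
unassigned.

Cell-cycle state from the G1/S and G2/M module scores:
cycling iff max(score) > 0.2; intermediate iff 0 < max <= 0.2; non-cycling
iff max <= 0.  Partial EMT requires both the epithelial and the
mesenchymal/CSC set-variation scores to strictly exceed 0.5.  Stemness
flags and CTA burden use detectable expression (raw count > 0).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MissingGenesError, ValidationError
from .io import ExpressionMatrix, GeneSetLibrary
from .scoring import module_score

log = logging.getLogger(__name__)

IMMUNE_PANELS = ("T", "B", "monocyte")
TUMOR_PANELS = ("epithelial", "lung")
CSC_MARKERS = ("PROM1", "CD44", "ALDH1A1", "ALDH1A3", "ALDH3A1", "ABCG2")

CellType = str  # one of: T, B, monocyte, CTC, unassigned
CycleState = str  # one of: cycling, intermediate, non_cycling


@dataclass
class CellAnnotation:
    """Per-cell table of type, cycle state, set scores, flags and CTA burden."""

    table: pd.DataFrame  # index cell_id


def _panel_positive(
    em: ExpressionMatrix,
    panel_genes: list[str],
    min_detected: int,
    score_threshold: float,
    rng: np.random.Generator,
    n_bins: int,
    n_ctrl: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (positive mask, module scores) for one panel; absent panel -> None."""
    gene_idx = em.gene_index()
    present = [g for g in panel_genes if g in gene_idx]
    if not present:
        return None, None
    idx = [gene_idx[g] for g in present]
    n_det = (em.values[idx, :] > 0).sum(axis=0)
    scores = module_score(em, present, n_bins=n_bins, n_ctrl=n_ctrl, rng=rng)
    positive = (n_det >= min_detected) | (scores > score_threshold)
    return positive, scores


def assign_cell_type(
    em: ExpressionMatrix,
    panels: GeneSetLibrary,
    min_detected: int = 2,
    score_threshold: float = 0.1,
    seed: int = 0,
    n_bins: int = 24,
    n_ctrl: int = 100,
) -> pd.DataFrame:
    """Type every cell as T / B / monocyte / CTC / unassigned.

    Returns a DataFrame indexed by cell_id with the call plus per-panel
    positivity and module-score columns for auditability.
    """
    rng = np.random.default_rng(seed)
    pos: dict[str, np.ndarray] = {}
    score: dict[str, np.ndarray] = {}
    for name in panels.names():
        p, s = _panel_positive(em, panels[name], min_detected, score_threshold, rng, n_bins, n_ctrl)
        if p is None:
            log.info("panel %r absent from matrix universe", name)
            continue
        pos[name], score[name] = p, s
    if not any(name in pos for name in TUMOR_PANELS):
        raise MissingGenesError("no tumor panel (epithelial/lung) gene present in matrix")

    n = em.n_cells
    immune_mask = np.zeros(n, dtype=bool)
    for name in IMMUNE_PANELS + ("leukocyte",):
        if name in pos:
            immune_mask |= pos[name]
    tumor_mask = np.zeros(n, dtype=bool)
    for name in TUMOR_PANELS:
        if name in pos:
            tumor_mask |= pos[name]

    immune_scores = np.vstack([score[p] for p in IMMUNE_PANELS if p in score])
    immune_names = [p for p in IMMUNE_PANELS if p in score]
    calls = np.full(n, "unassigned", dtype=object)
    if immune_names:
        best = np.array(immune_names, dtype=object)[np.argmax(immune_scores, axis=0)]
        calls[immune_mask] = best[immune_mask]
    calls[~immune_mask & tumor_mask] = "CTC"

    out = pd.DataFrame({"cell_type": calls}, index=pd.Index(em.cell_ids, name="cell_id"))
    for name in pos:
        out[f"{name}_positive"] = pos[name]
        out[f"{name}_score"] = score[name]
    return out


def assign_cycle_state(g1s: float, g2m: float) -> CycleState:
    """Three-way cycle call from the two phase scores (boundaries strict at 0.2)."""
    if np.isnan(g1s) or np.isnan(g2m):
        raise ValidationError("cycle scores must be finite, got NaN")
    top = max(g1s, g2m)
    if top > 0.2:
        return "cycling"
    if top > 0:
        return "intermediate"
    return "non_cycling"


def assign_cycle_states(g1s: np.ndarray, g2m: np.ndarray) -> np.ndarray:
    """Vectorized :func:`assign_cycle_state`."""
    g1s = np.asarray(g1s, dtype=float)
    g2m = np.asarray(g2m, dtype=float)
    if np.isnan(g1s).any() or np.isnan(g2m).any():
        raise ValidationError("cycle scores must be finite, got NaN")
    top = np.maximum(g1s, g2m)
    out = np.where(top > 0.2, "cycling", np.where(top > 0, "intermediate", "non_cycling"))
    return out.astype(object)


def classify_partial_emt(epi_score, mes_csc_score, threshold: float = 0.5):
    """Partial EMT: both state scores strictly above ``threshold``."""
    return (np.asarray(epi_score) > threshold) & (np.asarray(mes_csc_score) > threshold)


def csc_positivity(counts: np.ndarray, gene_ids: list[str], cell_ids: list[str]) -> pd.DataFrame:
    """Stemness-marker flags per cell; positivity = raw count > 0.

    Emits one boolean column per marker, the CD44+ALDH1A1+ dual flag, and the
    stem-like flag (PROM1+ or CD44+).  Markers absent from the universe give
    all-False columns and are logged.
    """
    gene_idx = {g: i for i, g in enumerate(gene_ids)}
    flags = {}
    for marker in CSC_MARKERS:
        if marker in gene_idx:
            flags[f"{marker}_pos"] = counts[gene_idx[marker], :] > 0
        else:
            log.info("CSC marker %s absent from universe", marker)
            flags[f"{marker}_pos"] = np.zeros(len(cell_ids), dtype=bool)
    df = pd.DataFrame(flags, index=pd.Index(cell_ids, name="cell_id"))
    df["CD44_ALDH1A1_dual"] = df["CD44_pos"] & df["ALDH1A1_pos"]
    df["stem_like"] = df["PROM1_pos"] | df["CD44_pos"]
    return df


def cta_burden(counts: np.ndarray, gene_ids: list[str], cta_list: list[str]) -> np.ndarray:
    """Number of detected (count > 0) CTA genes per cell."""
    gene_idx = {g: i for i, g in enumerate(gene_ids)}
    idx = [gene_idx[g] for g in cta_list if g in gene_idx]
    n_missing = len(cta_list) - len(idx)
    if n_missing:
        log.info("CTA burden: %d/%d list genes absent from universe", n_missing, len(cta_list))
    if not idx:
        return np.zeros(counts.shape[1], dtype=int)
    return (counts[idx, :] > 0).sum(axis=0).astype(int)


def panel_absence_profile(
    em: ExpressionMatrix,
    panels: GeneSetLibrary,
    sample_ids: pd.Series,
) -> pd.DataFrame:
    """Per sample x panel: fraction of cells detecting >= 1 panel gene.

    Panels with no gene in the universe are reported as NaN (absent from
    universe), distinct from 0.0 (present but never detected) — the
    distinction carries the evidence-of-origin logic for unknown-primary
    cases.
    """
    gene_idx = em.gene_index()
    sample_ids = pd.Series(sample_ids, index=em.cell_ids)
    rows = {}
    for name in panels.names():
        idx = [gene_idx[g] for g in panels[name] if g in gene_idx]
        if not idx:
            rows[name] = pd.Series(np.nan, index=sorted(sample_ids.unique()))
            continue
        det = (em.values[idx, :] > 0).any(axis=0)
        rows[name] = pd.Series(det, index=em.cell_ids).groupby(sample_ids).mean()
    return pd.DataFrame(rows).rename_axis("sample_id")
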