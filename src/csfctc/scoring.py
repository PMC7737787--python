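"""Gene-set scoring: module scores, single-sample rank enrichment (ssGSEA),
set-variation (GSVA-like) scores, and preranked GSEA.

These four constructions are the quantitative backbone of the cell-state
analysis.  The literature names the tools it uses for them but rarely the
algorithms; each procedure is therefore pinned down exactly here so results
are reproducible independent of any third-party package:

* **module_score** — per-cell mean expression of a set minus the mean of
  control genes drawn, per set gene, from the same average-expression bin
  (genes are ranked by dataset mean and cut into ``n_bins`` equal-size bins).
  This is the construction behind cell-cycle phase scores.
* **ssgsea_score** — per cell, genes are ranked by expression (average ranks
  on ties); the score is the sum over the descending-rank walk of the
  difference between the rank-weighted in-set ECDF (weights = rank^exponent)
  and the unweighted out-of-set ECDF.
* **gsva_like_score** — per cell, an unweighted Kolmogorov-Smirnov random
  walk over the within-cell ranking (+1/m in set, -1/(N-m) out); the raw
  score is the maximum-magnitude signed deviation, then min-max rescaled to
  [0, 1] across the cells of the analysis so a fixed 0.5 state cutoff is
  meaningful.
* **preranked_gsea** — weighted (exponent 1) running-sum enrichment score
  with gene-label permutations for nominal p, sign-matched NES, and a
  permutation FDR over all tested sets.

Ties in ranks always use average ranks; no scoring step breaks ties randomly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import DegenerateInputError, MissingGenesError, ValidationError
from .io import ExpressionMatrix, GeneSetLibrary, match_genes


@dataclass
class ScoreMatrix:
    """Set x cell score table plus the parameters that produced it."""

    scores: pd.DataFrame  # index set name, columns cell_ids
    score_kind: str  # module | ssgsea | gsva
    parameters: dict = field(default_factory=dict)


@dataclass
class EnrichmentResult:
    set_name: str
    es: float
    nes: float
    p_nominal: float
    fdr_q: float
    leading_edge: list[str]
    n_matched: int


# ---------------------------------------------------------------------------
# module score


def _expression_bins(mean_expr: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-size bins of genes by dataset-mean expression (stable order)."""
    order = np.argsort(mean_expr, kind="stable")
    bins = np.empty(len(mean_expr), dtype=int)
    bins[order] = (np.arange(len(mean_expr)) * n_bins) // len(mean_expr)
    return bins


def module_score(
    em: ExpressionMatrix,
    gene_set: list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Expression-matched control module score, one value per cell.

    For each set gene, ``n_ctrl`` control genes are drawn from the same
    average-expression bin without replacement (with replacement when the bin
    holds fewer than ``n_ctrl`` candidates); set genes are excluded from the
    control pool.  The score is mean(set) - mean(control pool).
    """
    if n_bins < 1 or n_ctrl < 1:
        raise ValidationError("n_bins and n_ctrl must be >= 1")
    matched = match_genes(gene_set, em.gene_ids, "module_score set")
    if not matched:
        raise MissingGenesError(f"no set genes present in matrix: {gene_set[:5]}...")
    if rng is None:
        rng = np.random.default_rng(seed)
    gene_idx = em.gene_index()
    # canonical (matrix) order so the control draw is invariant to set-gene order
    set_idx = np.sort(np.array([gene_idx[g] for g in matched]))
    mean_expr = em.values.mean(axis=1)
    bins = _expression_bins(mean_expr, n_bins)
    in_set = np.zeros(em.n_genes, dtype=bool)
    in_set[set_idx] = True

    ctrl_indices: list[np.ndarray] = []
    for gi in set_idx:
        pool = np.flatnonzero((bins == bins[gi]) & ~in_set)
        if pool.size == 0:
            continue
        replace = pool.size < n_ctrl
        ctrl_indices.append(rng.choice(pool, size=min(n_ctrl, pool.size) if not replace else n_ctrl, replace=replace))
    if not ctrl_indices:
        raise DegenerateInputError("no control genes available outside the set")
    ctrl = np.concatenate(ctrl_indices)
    return em.values[set_idx, :].mean(axis=0) - em.values[ctrl, :].mean(axis=0)


def cycle_scores(
    em: ExpressionMatrix,
    g1s_genes: list[str],
    g2m_genes: list[str],
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """G1/S and G2/M module scores sharing one binning and RNG stream."""
    rng = np.random.default_rng(seed)
    g1s = module_score(em, g1s_genes, n_bins=n_bins, n_ctrl=n_ctrl, rng=rng)
    g2m = module_score(em, g2m_genes, n_bins=n_bins, n_ctrl=n_ctrl, rng=rng)
    return g1s, g2m


def cycle_score_matrix(em, g1s_genes, g2m_genes, n_bins=24, n_ctrl=100, seed=0) -> ScoreMatrix:
    g1s, g2m = cycle_scores(em, g1s_genes, g2m_genes, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)
    df = pd.DataFrame([g1s, g2m], index=["G1S", "G2M"], columns=em.cell_ids)
    return ScoreMatrix(df, "module", {"n_bins": n_bins, "n_ctrl": n_ctrl, "seed": seed})


# ---------------------------------------------------------------------------
# ssGSEA


def _block_average(steps: np.ndarray, sorted_ranks: np.ndarray) -> np.ndarray:
    """Average step increments within tied-rank blocks.

    Makes rank walks invariant to the arbitrary within-tie order: every
    member of a tied block contributes the block's mean step, so the walk
    crosses a tie linearly instead of jumping wherever in-set genes happen
    to sort.
    """
    out = steps.astype(float).copy()
    n = len(steps)
    i = 0
    while i < n:
        j = i + 1
        while j < n and sorted_ranks[j] == sorted_ranks[i]:
            j += 1
        if j - i > 1:
            out[i:j] = out[i:j].mean()
        i = j
    return out


def ssgsea_score(em: ExpressionMatrix, gene_set: list[str], exponent: float = 0.25) -> np.ndarray:
    """Single-sample rank-enrichment score per cell.

    Per cell: average-rank the genes by expression (rank N = highest); walk
    genes in descending rank order (ties broken by gene index for a stable,
    deterministic order); at each step accumulate the rank^exponent-weighted
    in-set ECDF minus the unweighted out-of-set ECDF; the score is the sum of
    that difference over all steps.  Rank-invariant: cells with identical
    within-cell orderings score identically.
    """
    if exponent < 0:
        raise ValidationError("exponent must be >= 0")
    matched = match_genes(gene_set, em.gene_ids, "ssgsea set")
    if not matched:
        raise MissingGenesError(f"no set genes present in matrix: {gene_set[:5]}...")
    gene_idx = em.gene_index()
    in_set = np.zeros(em.n_genes, dtype=bool)
    in_set[[gene_idx[g] for g in matched]] = True
    n_genes, n_cells = em.values.shape
    n_out = n_genes - in_set.sum()
    if n_out == 0:
        raise DegenerateInputError("gene set covers the whole universe")
    scores = np.empty(n_cells)
    for c in range(n_cells):
        ranks = rankdata(em.values[:, c], method="average")
        order = np.lexsort((np.arange(n_genes), -ranks))  # descending rank, stable
        set_ord = in_set[order]
        sorted_ranks = ranks[order]
        w = np.where(set_ord, sorted_ranks**exponent, 0.0)
        denom = w.sum()
        in_steps = _block_average(w / denom, sorted_ranks)
        out_steps = _block_average((~set_ord) / n_out, sorted_ranks)
        scores[c] = np.sum(np.cumsum(in_steps) - np.cumsum(out_steps))
    return scores


# ---------------------------------------------------------------------------
# GSVA-like set-variation score


def _ks_walk_raw(ranks: np.ndarray, in_set: np.ndarray) -> float:
    """Signed maximum deviation of the unweighted KS walk over descending ranks.

    Tied blocks contribute their average step per position, so the walk is
    invariant to within-tie order.
    """
    n = len(ranks)
    m = int(in_set.sum())
    order = np.lexsort((np.arange(n), -ranks))
    set_ord = in_set[order]
    sorted_ranks = ranks[order]
    steps = _block_average(np.where(set_ord, 1.0 / m, -1.0 / (n - m)), sorted_ranks)
    walk = np.cumsum(steps)
    i = int(np.argmax(np.abs(walk)))
    return float(walk[i])


def gsva_like_score(em: ExpressionMatrix, sets: GeneSetLibrary) -> ScoreMatrix:
    """Per-set per-cell KS-walk scores, min-max rescaled to [0, 1] across cells.

    The raw score is the signed maximum-magnitude deviation of the random
    walk over the within-cell gene ranking (+1/m on set genes, -1/(N-m)
    otherwise).  Rescaling across the cells of the analysis makes a fixed
    0.5 cutoff usable as a state call; a set with identical raw scores in
    every cell rescales to 0.5 everywhere.
    """
    if em.n_cells < 2:
        raise DegenerateInputError("gsva-like rescaling needs >= 2 cells")
    gene_idx = em.gene_index()
    rank_cache = np.empty_like(em.values)
    for c in range(em.n_cells):
        rank_cache[:, c] = rankdata(em.values[:, c], method="average")
    rows = {}
    raw_rows = {}
    for name in sets.names():
        matched = match_genes(sets[name], em.gene_ids, f"gsva set {name}")
        if not matched:
            raise MissingGenesError(f"set {name!r} has no genes in the matrix")
        in_set = np.zeros(em.n_genes, dtype=bool)
        in_set[[gene_idx[g] for g in matched]] = True
        if in_set.all():
            raise DegenerateInputError(f"set {name!r} covers the whole universe")
        raw = np.array([_ks_walk_raw(rank_cache[:, c], in_set) for c in range(em.n_cells)])
        lo, hi = raw.min(), raw.max()
        rows[name] = (raw - lo) / (hi - lo) if hi > lo else np.full_like(raw, 0.5)
        raw_rows[name] = raw
    df = pd.DataFrame(rows, index=em.cell_ids).T
    sm = ScoreMatrix(df, "gsva", {"weight": 1, "rescale": "minmax"})
    sm.parameters["raw"] = pd.DataFrame(raw_rows, index=em.cell_ids).T
    return sm


# ---------------------------------------------------------------------------
# preranked GSEA


def _es_and_walk(weights_abs: np.ndarray, in_set: np.ndarray) -> tuple[float, np.ndarray]:
    """Weighted (exponent 1) running-sum ES over an ordered ranking."""
    n_out = len(in_set) - int(in_set.sum())
    hit_w = np.where(in_set, weights_abs, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all in-set weights zero: fall back to unweighted hits
        hit_w = in_set.astype(float)
        denom = hit_w.sum()
    p_hit = np.cumsum(hit_w) / denom
    p_miss = np.cumsum(~in_set) / n_out
    walk = p_hit - p_miss
    i = int(np.argmax(np.abs(walk)))
    return float(walk[i]), walk


def preranked_gsea(
    ranking: list[tuple[str, float]],
    sets: GeneSetLibrary,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Preranked GSEA with gene-label permutations.

    ``ranking`` is a gene list ordered from most up- to most down-weighted
    with real weights (e.g. signed log2 fold changes).  ES uses the weighted
    running sum (weight exponent 1); nominal p is one-sided within the sign
    of the observed ES; NES divides ES by the mean |permuted ES| of matching
    sign; FDR q is the standard permutation estimate pooled over all tested
    sets.  Sets with no genes in the ranking are skipped.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    genes = [g for g, _ in ranking]
    if len(set(genes)) != len(genes):
        raise ValidationError("ranking contains duplicate genes")
    weights = np.abs(np.array([w for _, w in ranking], dtype=float))
    n = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    tested: list[tuple[str, float, list[str], np.ndarray]] = []
    for name in sets.names():
        members = [g for g in sets[name] if g in gene_pos]
        if not members:
            import logging

            logging.getLogger(__name__).warning("set %r has no genes in ranking; skipped", name)
            continue
        if len(members) == n:
            raise DegenerateInputError(f"set {name!r} covers the whole ranking")
        in_set = np.zeros(n, dtype=bool)
        in_set[[gene_pos[g] for g in members]] = True
        es, walk = _es_and_walk(weights, in_set)
        peak = int(np.argmax(np.abs(walk)))
        if es >= 0:
            leading = [genes[i] for i in range(peak + 1) if in_set[i]]
        else:
            leading = [genes[i] for i in range(peak, n) if in_set[i]]
        m = len(members)
        perm_es = np.empty(n_perm)
        for p in range(n_perm):
            perm = np.zeros(n, dtype=bool)
            perm[rng.choice(n, size=m, replace=False)] = True
            perm_es[p], _ = _es_and_walk(weights, perm)
        tested.append((name, es, leading, perm_es))

    # NES and nominal p per set, sign-matched
    results = []
    all_nes_perm: list[np.ndarray] = []
    nes_obs = []
    for name, es, leading, perm_es in tested:
        same_sign = perm_es[perm_es >= 0] if es >= 0 else -perm_es[perm_es < 0]
        if same_sign.size == 0:
            p_nom, nes = 1.0 / (n_perm + 1), 0.0
            nes_perm = np.array([])
        else:
            p_nom = (1 + np.sum(same_sign >= abs(es))) / (1 + same_sign.size)
            mean_mag = same_sign.mean()
            nes = es / mean_mag if mean_mag > 0 else 0.0
            nes_perm = np.sign(es) * same_sign / mean_mag if mean_mag > 0 else np.array([])
        nes_obs.append(nes)
        all_nes_perm.append(nes_perm)
        results.append([name, es, nes, p_nom, leading])

    pooled = np.concatenate(all_nes_perm) if all_nes_perm else np.array([])
    nes_arr = np.array(nes_obs)
    out = []
    for (name, es, nes, p_nom, leading) in results:
        if pooled.size == 0:
            q = 1.0
        elif nes >= 0:
            num = np.mean(pooled >= nes) if (pooled >= 0).any() else 0.0
            den = np.mean(nes_arr >= nes)
            q = num / den if den > 0 else 1.0
        else:
            num = np.mean(pooled <= nes) if (pooled < 0).any() else 0.0
            den = np.mean(nes_arr <= nes)
            q = num / den if den > 0 else 1.0
        q = float(min(max(q, 0.0), 1.0))
        out.append(
            EnrichmentResult(
                set_name=name,
                es=float(es),
                nes=float(nes),
                p_nominal=float(p_nom),
                fdr_q=q,
                leading_edge=leading,
                n_matched=len([g for g in sets[name] if g in gene_pos]),
            )
        )
    return out
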