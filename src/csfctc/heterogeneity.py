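"""Transcriptome heterogeneity via pairwise cell-cell correlations.

Heterogeneity is read off the distribution of pairwise correlation
coefficients between single-cell expression profiles: a *lower* mean
correlation means *greater* heterogeneity.  Within-group (intra) pairs are
compared to between-group (inter) pairs with a two-sided Wilcoxon rank-sum
test.  The test treats pairs as exchangeable observations even though pairs
share cells; an optional cell-level permutation p-value is provided as a
robustness check on that simplification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from .errors import DegenerateInputError, ValidationError
from .io import ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    values: pd.DataFrame  # cell x cell, symmetric, unit diagonal (NaN for zero-variance cells)
    method: str
    gene_universe: list[str]


@dataclass
class HeterogeneitySummary:
    intra_mean_by_group: dict[str, float]
    intra_mean: float
    inter_mean: float | None
    n_intra_pairs: int
    n_inter_pairs: int
    wilcoxon_stat: float | None
    p_value: float | None
    greater_heterogeneity: str | None  # which pair class has the lower mean coefficient
    notes: list[str] = field(default_factory=list)


def pairwise_correlation(
    em: ExpressionMatrix,
    method: str = "pearson",
    gene_subset: list[str] | None = None,
) -> CorrelationMatrix:
    """Cell x cell correlation over the gene universe (default: all genes).

    Cells with zero variance over the universe produce NaN rows/columns,
    reported with a logged count rather than an error.
    """
    if em.n_cells < 2:
        raise DegenerateInputError("pairwise correlation needs >= 2 cells")
    if gene_subset is not None:
        gene_idx = em.gene_index()
        idx = [gene_idx[g] for g in gene_subset if g in gene_idx]
        if len(idx) < 2:
            raise DegenerateInputError("gene_subset matches < 2 genes")
        values = em.values[idx, :]
        universe = [em.gene_ids[i] for i in idx]
    else:
        values = em.values
        universe = list(em.gene_ids)
    if method == "spearman":
        values = np.apply_along_axis(rankdata, 0, values)
    elif method != "pearson":
        raise ValidationError(f"unknown correlation method {method!r}")
    sd = values.std(axis=0)
    degenerate = sd == 0
    if degenerate.any():
        log.warning("%d cells with zero variance over the universe; correlations NaN", degenerate.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values, rowvar=False)
    corr[degenerate, :] = np.nan
    corr[:, degenerate] = np.nan
    np.fill_diagonal(corr, np.where(degenerate, np.nan, 1.0))
    df = pd.DataFrame(corr, index=em.cell_ids, columns=em.cell_ids)
    return CorrelationMatrix(values=df, method=method, gene_universe=universe)


def _pair_sets(corr: CorrelationMatrix, groups: pd.Series):
    cells = list(corr.values.index)
    g = pd.Series(groups).loc[cells].to_numpy()
    mat = corr.values.to_numpy()
    iu = np.triu_indices(len(cells), k=1)
    same = g[iu[0]] == g[iu[1]]
    vals = mat[iu]
    return vals, same, g, iu


def heterogeneity_summary(corr: CorrelationMatrix, groups: pd.Series) -> HeterogeneitySummary:
    """Intra- vs inter-group mean correlation with a two-sided rank-sum test.

    ``groups`` maps every cell of the correlation matrix to a group (e.g.
    patient).  NaN pairs (zero-variance cells) are excluded with a note.
    With a single group, inter statistics and the test are reported absent,
    not fabricated.
    """
    missing = set(corr.values.index) - set(pd.Series(groups).index)
    if missing:
        raise ValidationError(f"cells without group labels: {sorted(missing)[:5]}")
    vals, same, g, iu = _pair_sets(corr, groups)
    notes = []
    ok = ~np.isnan(vals)
    if (~ok).any():
        notes.append(f"{(~ok).sum()} pairs with NaN correlation excluded")
    intra = vals[same & ok]
    inter = vals[~same & ok]
    labels = g[iu[0]]
    intra_by_group = {}
    for grp in pd.unique(g):
        mask = same & ok & (labels == grp)
        intra_by_group[str(grp)] = float(vals[mask].mean()) if mask.any() else float("nan")
    n_groups = len(pd.unique(g))
    if n_groups < 2:
        return HeterogeneitySummary(
            intra_mean_by_group=intra_by_group,
            intra_mean=float(intra.mean()) if intra.size else float("nan"),
            inter_mean=None,
            n_intra_pairs=int(same.sum()),
            n_inter_pairs=0,
            wilcoxon_stat=None,
            p_value=None,
            greater_heterogeneity=None,
            notes=notes + ["single group: inter statistics undefined"],
        )
    stat, p = mannwhitneyu(intra, inter, alternative="two-sided")
    intra_mean = float(intra.mean())
    inter_mean = float(inter.mean())
    side = "inter" if inter_mean < intra_mean else "intra"
    return HeterogeneitySummary(
        intra_mean_by_group=intra_by_group,
        intra_mean=intra_mean,
        inter_mean=inter_mean,
        n_intra_pairs=int(same.sum()),
        n_inter_pairs=int((~same).sum()),
        wilcoxon_stat=float(stat),
        p_value=float(p),
        greater_heterogeneity=side,
        notes=notes,
    )


def cell_permutation_p(
    corr: CorrelationMatrix,
    groups: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
) -> float:
    """Cell-label permutation p for the intra-inter mean gap (robustness check).

    Permutes group labels over cells (not pairs), honoring the dependence
    between pairs sharing a cell, and compares |intra_mean - inter_mean|
    against its permutation distribution.
    """
    vals, same, g, iu = _pair_sets(corr, groups)
    ok = ~np.isnan(vals)

    def gap(same_mask):
        a = vals[same_mask & ok]
        b = vals[~same_mask & ok]
        if not a.size or not b.size:
            return 0.0
        return abs(a.mean() - b.mean())

    obs = gap(same)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(g)
        count += gap(perm[iu[0]] == perm[iu[1]]) >= obs
    return (1 + count) / (1 + n_perm)
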