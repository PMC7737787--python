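"""Two-group differential expression, patient signatures, stage-biased genes,
and diagnostic panel selection.

The default per-gene test is the two-sided Wilcoxon rank-sum on
log-normalized expression (tie-corrected normal approximation, exact when
the smaller group has fewer than 8 cells and no ties permit it), with
Benjamini-Hochberg adjustment over all tested genes.  A simplified
negative-binomial Wald test (method-of-moments dispersion on library-size
scaled counts) is available as an alternative; the method used is recorded
in the output.

Fold changes are log2 of the ratio of group mean CP10K expression with a
pseudocount (default 1) on both means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError, ValidationError
from .io import CountMatrix


@dataclass
class PanelCriteria:
    """Thresholds for diagnostic panel selection (all four must pass)."""

    min_detect_frac_ctc: float = 0.5
    max_detect_frac_normal: float = 0.05
    min_log2_fc: float = 1.0
    max_p_adj: float = 0.05
    panel_size: int = 20

    def validate(self):
        for f in (self.min_detect_frac_ctc, self.max_detect_frac_normal):
            if not 0 <= f <= 1:
                raise ValidationError("detection fractions must be in [0, 1]")
        if self.panel_size < 1:
            raise ValidationError("panel_size must be >= 1")
        return self


def _cp10k_means(counts: np.ndarray, scale: float = 1e4) -> np.ndarray:
    totals = counts.sum(axis=0).astype(float)
    safe = np.where(totals > 0, totals, 1.0)
    return (scale * counts / safe[None, :]).mean(axis=1)


def _nb_wald_p(counts_a: np.ndarray, counts_b: np.ndarray) -> np.ndarray:
    """Simplified NB Wald test on library-size scaled counts.

    Per gene: scale counts to the mean library size, estimate a common
    method-of-moments dispersion, and test the difference of group means
    with a normal Wald statistic using Var(X) = mu + mu^2/theta.
    """
    all_counts = np.hstack([counts_a, counts_b])
    lib = all_counts.sum(axis=0).astype(float)
    sf = lib / lib.mean() if lib.mean() > 0 else np.ones_like(lib)
    sf = np.where(sf > 0, sf, 1.0)
    scaled = all_counts / sf[None, :]
    na, nb = counts_a.shape[1], counts_b.shape[1]
    sa, sb = scaled[:, :na], scaled[:, na:]
    mu = scaled.mean(axis=1)
    var = scaled.var(axis=1, ddof=1)
    # Var = mu + mu^2/theta  =>  1/theta = (Var - mu)/mu^2, floored at 0
    inv_theta = np.clip((var - mu) / np.maximum(mu, 1e-12) ** 2, 0.0, None)
    ma, mb = sa.mean(axis=1), sb.mean(axis=1)
    va = (ma + inv_theta * ma**2) / na
    vb = (mb + inv_theta * mb**2) / nb
    se = np.sqrt(va + vb)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(se > 0, (ma - mb) / se, 0.0)
    return 2 * stats.norm.sf(np.abs(z))


def de_two_group(
    cm: CountMatrix,
    group_a: list[str],
    group_b: list[str],
    method: str = "ranksum",
    epsilon: float = 1.0,
    scale_factor: float = 1e4,
) -> pd.DataFrame:
    """Per-gene two-group differential expression with BH-FDR.

    Returns a DataFrame indexed by gene with mean_a/mean_b (CP10K means),
    detect_frac_a/b, log2_fc (positive = up in group_a), p_raw and p_adj.
    Groups must be disjoint with at least 3 cells each.
    """
    set_a, set_b = set(group_a), set(group_b)
    if set_a & set_b:
        raise ValidationError(f"groups overlap: {sorted(set_a & set_b)[:5]}")
    missing = (set_a | set_b) - set(cm.cell_ids)
    if missing:
        raise ValidationError(f"cells not in matrix: {sorted(missing)[:5]}")
    if len(group_a) < 3 or len(group_b) < 3:
        raise DegenerateInputError("each group needs >= 3 cells")
    if method not in ("ranksum", "nb_wald"):
        raise ValidationError(f"unknown method {method!r}")

    pos = {c: i for i, c in enumerate(cm.cell_ids)}
    ia = [pos[c] for c in group_a]
    ib = [pos[c] for c in group_b]
    counts_a = cm.counts[:, ia]
    counts_b = cm.counts[:, ib]

    totals = cm.counts.sum(axis=0).astype(float)
    safe = np.where(totals > 0, totals, 1.0)
    cp10k = scale_factor * cm.counts / safe[None, :]
    mean_a = cp10k[:, ia].mean(axis=1)
    mean_b = cp10k[:, ib].mean(axis=1)

    if method == "ranksum":
        logn = np.log1p(cp10k)
        small = min(len(ia), len(ib))
        use_exact = small < 8
        p = np.empty(cm.n_genes)
        for g in range(cm.n_genes):
            xa, xb = logn[g, ia], logn[g, ib]
            if np.all(xa == xa[0]) and np.all(xb == xb[0]) and xa[0] == xb[0]:
                p[g] = 1.0
                continue
            m = "exact" if use_exact and len(np.unique(np.concatenate([xa, xb]))) == len(xa) + len(xb) else "asymptotic"
            p[g] = stats.mannwhitneyu(xa, xb, alternative="two-sided", method=m).pvalue
    else:
        p = _nb_wald_p(counts_a, counts_b)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")

    table = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "detect_frac_a": (counts_a > 0).mean(axis=1),
            "detect_frac_b": (counts_b > 0).mean(axis=1),
            "log2_fc": np.log2((mean_a + epsilon) / (mean_b + epsilon)),
            "p_raw": p,
            "p_adj": p_adj,
        },
        index=pd.Index(cm.gene_ids, name="gene_id"),
    )
    table.attrs["method"] = method
    table.attrs["epsilon"] = epsilon
    return table


def patient_signatures(
    cm: CountMatrix,
    patient_labels: pd.Series,
    p_cutoff: float = 0.05,
    fc_cutoff: float = 1.5,
    method: str = "ranksum",
) -> dict[str, list[str]]:
    """One-vs-rest signature genes per patient (raw p < cutoff, FC > cutoff).

    The raw-p criterion is deliberate: per-patient signature discovery uses
    unadjusted p with a 1.5-fold change, a more permissive screen than the
    two-group DEG call.
    """
    labels = pd.Series(patient_labels).loc[cm.cell_ids]
    patients = sorted(labels.unique())
    if len(patients) < 2:
        raise ValidationError("patient signatures need >= 2 patients")
    log2_cut = np.log2(fc_cutoff)
    out = {}
    for p in patients:
        cells_in = [c for c, l in labels.items() if l == p]
        cells_out = [c for c, l in labels.items() if l != p]
        de = de_two_group(cm, cells_in, cells_out, method=method)
        hits = de[(de["p_raw"] < p_cutoff) & (de["log2_fc"] > log2_cut)]
        out[str(p)] = list(hits.sort_values("log2_fc", ascending=False).index)
    return out


def stage_biased_genes(
    cm: CountMatrix,
    stage_labels: pd.Series,
    early: str,
    late: str,
    p_adj_cutoff: float = 0.05,
    fc_cutoff: float = 2.0,
    method: str = "ranksum",
) -> dict[str, list[str]]:
    """Signed DEG lists between two disease stages (adjusted p, FC > 2).

    Returns {'up_in_late': [...], 'up_in_early': [...]}.
    """
    labels = pd.Series(stage_labels).loc[cm.cell_ids]
    cells_early = [c for c, l in labels.items() if l == early]
    cells_late = [c for c, l in labels.items() if l == late]
    de = de_two_group(cm, cells_late, cells_early, method=method)
    log2_cut = np.log2(fc_cutoff)
    sig = de[de["p_adj"] < p_adj_cutoff]
    return {
        "up_in_late": list(sig[sig["log2_fc"] > log2_cut].sort_values("log2_fc", ascending=False).index),
        "up_in_early": list(sig[sig["log2_fc"] < -log2_cut].sort_values("log2_fc").index),
    }


def select_panel(de: pd.DataFrame, criteria: PanelCriteria) -> pd.DataFrame:
    """Rank-ordered diagnostic gene panel from a CTC-vs-normal DE table.

    Genes passing all four criteria, ranked by detection gap
    (detect_frac_a - detect_frac_b) descending, ties by log2_fc descending
    then gene ID, truncated to ``panel_size``.  An empty result is a warning,
    not an error.
    """
    criteria.validate()
    passing = de[
        (de["detect_frac_a"] >= criteria.min_detect_frac_ctc)
        & (de["detect_frac_b"] <= criteria.max_detect_frac_normal)
        & (de["log2_fc"] >= criteria.min_log2_fc)
        & (de["p_adj"] < criteria.max_p_adj)
    ].copy()
    if passing.empty:
        import logging

        logging.getLogger(__name__).warning("no gene passed the panel criteria; empty panel")
        return passing
    passing["detect_gap"] = passing["detect_frac_a"] - passing["detect_frac_b"]
    passing = (
        passing.reset_index()
        .sort_values(by=["detect_gap", "log2_fc", "gene_id"], ascending=[False, False, True])
        .set_index("gene_id")
    )
    return passing.head(criteria.panel_size)
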