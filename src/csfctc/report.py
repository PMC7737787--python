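"""Cohort summaries, fixed-precision proportion reporting, pipeline
orchestration, and a convenience 2-D embedding.

Every percentage in any output is emitted together with its integer
numerator and denominator and is recomputable via :func:`report_proportion`
(100*n/d, rounded half-up to one decimal — half-up, not banker's, because
the two differ on real inputs and reported ratios must be audit-stable).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import datasets
from .classify import (
    assign_cell_type,
    assign_cycle_states,
    classify_partial_emt,
    csc_positivity,
    cta_burden,
)
from .diffexpr import de_two_group
from .errors import DegenerateInputError, ValidationError
from .heterogeneity import heterogeneity_summary, pairwise_correlation
from .io import CountMatrix, load_counts, normalize, write_counts
from .qc import compute_qc, run_qc
from .scoring import cycle_scores, gsva_like_score
from .synthdata import SyntheticConfig, generate

log = logging.getLogger(__name__)


def report_proportion(numerator: int, denominator: int) -> float:
    """100*n/d rounded half-up to one decimal (e.g. 162/967 -> 16.8)."""
    if denominator <= 0:
        raise ValidationError("denominator must be positive")
    if not 0 <= numerator <= denominator:
        raise ValidationError("numerator must be in [0, denominator]")
    pct = Decimal(100 * numerator) / Decimal(denominator)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class CohortSummary:
    per_sample: pd.DataFrame  # cell-type counts per sample
    per_patient: dict  # cycle proportions, flags, CTA quartiles
    across_patient_means: dict
    metadata: dict = field(default_factory=dict)


def summarize_cohort(
    annotations: pd.DataFrame,
    qc_per_cell: pd.DataFrame,
    sample_ids: pd.Series,
    patient_ids: pd.Series,
    n_sequenced: dict[str, int] | None = None,
) -> CohortSummary:
    """Tabulate class counts per sample and state proportions per patient.

    ``annotations`` must cover exactly the QC-passing cells and carry
    cell_type; cycle_state / partial_emt / cta_count columns are summarized
    when present.  Per-patient percentages are also averaged unweighted
    across patients ("on average" convention).
    """
    cells = list(annotations.index)
    if set(cells) != set(qc_per_cell.index):
        raise ValidationError("annotations and QC metrics cover different cell sets")
    samples = pd.Series(sample_ids).loc[cells]
    patients = pd.Series(patient_ids).loc[cells]

    type_counts = (
        annotations["cell_type"]
        .groupby(samples)
        .value_counts()
        .unstack(fill_value=0)
        .rename_axis("sample_id")
    )
    type_counts["qc_filtered"] = type_counts.sum(axis=1)
    if n_sequenced:
        type_counts["sequenced"] = pd.Series(n_sequenced)

    per_patient: dict[str, dict] = {}
    for pid in sorted(patients.unique()):
        mask = patients == pid
        sub = annotations.loc[mask.to_numpy()]
        entry: dict = {"n_cells": int(mask.sum())}
        ctc = sub[sub["cell_type"] == "CTC"]
        entry["n_ctc"] = len(ctc)
        if "cycle_state" in sub.columns and len(ctc):
            n_cyc = int((ctc["cycle_state"] == "cycling").sum())
            entry["cycling"] = {
                "numerator": n_cyc,
                "denominator": len(ctc),
                "percent": report_proportion(n_cyc, len(ctc)),
            }
        if "partial_emt" in sub.columns and len(ctc):
            n_emt = int(ctc["partial_emt"].sum())
            entry["partial_emt"] = {
                "numerator": n_emt,
                "denominator": len(ctc),
                "percent": report_proportion(n_emt, len(ctc)),
            }
        for col in sub.columns:
            if col.endswith("_pos") or col.endswith("_dual") or col == "stem_like":
                if len(ctc):
                    n_pos = int(ctc[col].sum())
                    entry[col] = {
                        "numerator": n_pos,
                        "denominator": len(ctc),
                        "percent": report_proportion(n_pos, len(ctc)),
                    }
        if "cta_count" in sub.columns and len(ctc):
            q = ctc["cta_count"].quantile([0.25, 0.5, 0.75])
            entry["cta_quartiles"] = [float(q[0.25]), float(q[0.5]), float(q[0.75])]
        per_patient[str(pid)] = entry

    across: dict[str, float] = {}
    for key in ("cycling", "partial_emt"):
        pcts = [e[key]["percent"] for e in per_patient.values() if key in e]
        if pcts:
            across[key] = float(
                (Decimal(str(sum(pcts))) / Decimal(len(pcts))).quantize(
                    Decimal("0.1"), rounding=ROUND_HALF_UP
                )
            )
    return CohortSummary(
        per_sample=type_counts,
        per_patient=per_patient,
        across_patient_means=across,
    )


def embed_cells(em, method: str = "tsne", seed: int = 0) -> pd.DataFrame:
    """Convenience 2-D embedding for visualization only (no quantitative use)."""
    if em.n_cells < 3:
        raise DegenerateInputError("embedding needs >= 3 cells")
    x = em.values.T
    if method == "tsne":
        from sklearn.decomposition import PCA
        from sklearn.manifold import TSNE

        n_pc = int(min(30, x.shape[0] - 1, x.shape[1]))
        x = PCA(n_components=n_pc, random_state=seed).fit_transform(x)
        perplexity = min(30.0, (em.n_cells - 1) / 3)
        coords = TSNE(
            n_components=2, random_state=seed, perplexity=perplexity, init="pca"
        ).fit_transform(x)
    elif method == "pca":
        from sklearn.decomposition import PCA

        coords = PCA(n_components=2, random_state=seed).fit_transform(x)
    else:
        raise ValidationError(f"unknown embedding method {method!r}")
    return pd.DataFrame(coords, index=pd.Index(em.cell_ids, name="cell_id"), columns=["dim1", "dim2"])


# ---------------------------------------------------------------------------
# pipeline orchestration

DEFAULT_CONFIG: dict = {
    "input": None,  # path to counts (mtx dir or tsv); None -> simulate
    "input_format": "mtx",
    "simulate": None,  # SyntheticConfig fields
    "qc": {"min_cells": 10, "min_genes": 600, "max_mito": 0.20},
    "high_coverage_min_genes": 1000,
    "normalize": {"scale_factor": 1e4},
    "typing": {"min_detected": 2, "score_threshold": 0.1},
    "cycle": {"n_bins": 24, "n_ctrl": 100},
    "partial_emt_threshold": 0.5,
    "heterogeneity": {"method": "pearson", "group_by": "patient_id"},
    "de": {"method": "ranksum", "epsilon": 1.0},
    "embedding": False,
    "seed": 0,
    "out_dir": "results/run",
}


@dataclass
class RunConfig:
    """Validated pipeline configuration (unknown keys rejected)."""

    options: dict

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        merged = {}
        for key, default in DEFAULT_CONFIG.items():
            val = raw.get(key, default)
            if isinstance(default, dict) and isinstance(val, dict):
                bad = set(val) - set(default)
                if bad:
                    raise ValidationError(f"unknown config keys under {key!r}: {sorted(bad)}")
                val = {**default, **val}
            merged[key] = val
        return cls(options=merged)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> Path:
    """QC -> scoring -> typing -> states -> heterogeneity -> summary.

    Writes TSV tables and a JSON run summary (config echo, stage timings,
    seeds, artifact hashes) into the output directory and returns its path.
    """
    opt = config.options
    out = Path(out_dir if out_dir is not None else opt["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(opt["seed"])
    timings: dict[str, float] = {}

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, *exc):
                timings[name] = round(time.perf_counter() - self.t0, 3)

        return _T()

    with stage("load"):
        if opt["input"] is not None:
            cm = load_counts(opt["input"], format=opt["input_format"])
        else:
            sim_cfg = SyntheticConfig(**{**(opt["simulate"] or {}), "seed": seed})
            cm, truth = generate(sim_cfg)
            truth.cells.to_csv(out / "truth_cells.tsv", sep="\t")
            write_counts(cm, out / "counts", format="mtx")

    with stage("qc"):
        cm_qc, qc = run_qc(cm, **opt["qc"])
        qc.per_cell.loc[cm_qc.cell_ids].to_csv(out / "qc_metrics.tsv", sep="\t")
    if cm_qc.n_cells < 3:
        raise DegenerateInputError("fewer than 3 cells survive QC")

    with stage("normalize"):
        em = normalize(cm_qc, **opt["normalize"])

    with stage("typing"):
        panels = datasets.marker_panels()
        ann = assign_cell_type(em, panels, seed=seed, **opt["typing"])

    with stage("states"):
        g1s_genes, g2m_genes = datasets.cell_cycle_sets()
        g1s, g2m = cycle_scores(em, g1s_genes, g2m_genes, seed=seed, **opt["cycle"])
        ann["g1s_score"], ann["g2m_score"] = g1s, g2m
        ann["cycle_state"] = assign_cycle_states(g1s, g2m)
        emt_lib = datasets.emt_sets()
        sm = gsva_like_score(em, emt_lib)
        ann["epi_score"] = sm.scores.loc["epithelial7"].to_numpy()
        ann["mes_csc_score"] = sm.scores.loc["mes_csc"].to_numpy()
        ann["ecm_score"] = sm.scores.loc["ecm"].to_numpy()
        ann["partial_emt"] = classify_partial_emt(
            ann["epi_score"], ann["mes_csc_score"], threshold=opt["partial_emt_threshold"]
        )
        flags = csc_positivity(cm_qc.counts, cm_qc.gene_ids, cm_qc.cell_ids)
        ann = ann.join(flags)
        ann["cta_count"] = cta_burden(cm_qc.counts, cm_qc.gene_ids, datasets.cta_list())
        ann.to_csv(out / "cell_annotations.tsv", sep="\t")

    with stage("heterogeneity"):
        ctc_cells = ann.index[ann["cell_type"] == "CTC"]
        het = None
        if len(ctc_cells) >= 2:
            em_ctc_mask = np.isin(em.cell_ids, ctc_cells)
            from .io import ExpressionMatrix

            em_ctc = ExpressionMatrix(
                values=em.values[:, em_ctc_mask],
                gene_ids=em.gene_ids,
                cell_ids=[c for c, m in zip(em.cell_ids, em_ctc_mask) if m],
                source_total=em.source_total[em_ctc_mask],
                scale_factor=em.scale_factor,
            )
            corr = pairwise_correlation(em_ctc, method=opt["heterogeneity"]["method"])
            groups = cm_qc.cell_meta[opt["heterogeneity"]["group_by"]]
            het = heterogeneity_summary(corr, groups)

    if opt["embedding"]:
        with stage("embedding"):
            embed_cells(em, seed=seed).to_csv(out / "embedding.tsv", sep="\t")

    with stage("summary"):
        qc_all = compute_qc(cm_qc)
        summary = summarize_cohort(
            ann,
            qc_all.per_cell,
            cm_qc.cell_meta["sample_id"],
            cm_qc.cell_meta["patient_id"],
        )
        summary.per_sample.to_csv(out / "cohort_per_sample.tsv", sep="\t")

    artifacts = sorted(p.name for p in out.glob("*.tsv"))
    hashes = {
        name: hashlib.sha256((out / name).read_bytes()).hexdigest()[:16] for name in artifacts
    }
    log.info("stage timings (s): %s", timings)
    run_summary = {
        "config": _jsonable(opt),
        "seed": seed,
        "n_cells_input": cm.n_cells,
        "n_cells_qc": cm_qc.n_cells,
        "n_genes_qc": cm_qc.n_genes,
        "per_patient": summary.per_patient,
        "across_patient_means": summary.across_patient_means,
        "heterogeneity": None
        if het is None
        else {
            "intra_mean": het.intra_mean,
            "inter_mean": het.inter_mean,
            "p_value": het.p_value,
            "greater_heterogeneity": het.greater_heterogeneity,
        },
        "artifact_hashes": hashes,
    }
    (out / "run_summary.json").write_text(json.dumps(run_summary, indent=2, sort_keys=True))
    return out


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj
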