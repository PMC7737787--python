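"""Smart-seq2-like count simulator with planted cell-type, patient, cycle,
EMT and CTA structure.

The generator emulates the statistical shape of CSF single-cell read-count
data: negative-binomial counts (variance mu + mu^2/theta) thinned by
independent Bernoulli dropout, several hundred to ~two thousand detected
genes per cell, a mitochondrial load calibrated to a target fraction, and
distinct expression programs for immune populations, tumor cells, cycling
cells, partial-EMT cells, and individual patients.  Every planted label and
parameter is emitted as a :class:`SyntheticTruth`, which is the oracle for
every downstream stage.

Program structure: gene means are ``baseline * 2^(sum of active effects)``.
Marker and program genes carry a positive on-lineage effect (default +3
log2, an 8-fold shift) and a negative off-lineage effect (default -12 log2,
i.e. ~0.001 expected reads per cell — the stray-read residual of
index hopping / ambient contamination in FACS-sorted Smart-seq2 data).
Off-lineage suppression reflects the biology the typing rule relies on:
lineage markers are effectively silent outside their lineage, and a single
stray marker read is enough to flip a small panel's module score, so marker
off-lineage means must sit at stray-read level for typing to be definable
at all.

All randomness flows from one ``numpy.random.default_rng(seed)`` (PCG64)
stream; identical config + seed reproduces matrices and truth bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import datasets
from .errors import ValidationError
from .io import CountMatrix

MT_GENES = [
    "MT-ND1", "MT-ND2", "MT-ND3", "MT-ND4", "MT-ND4L", "MT-ND5", "MT-ND6",
    "MT-CO1", "MT-CO2", "MT-CO3", "MT-ATP6", "MT-ATP8", "MT-CYB",
]

POPULATIONS = ("T", "B", "monocyte", "CTC")

# absolute baseline means for the rare-stemness markers (PROM1/ABCG2 nearly
# absent, ALDH family sporadically detected — the regime the flag analysis targets)
CSC_BASELINES = {"PROM1": 0.01, "ABCG2": 0.01, "ALDH1A1": 0.3, "ALDH1A3": 0.15, "ALDH3A1": 0.15}


@dataclass
class SyntheticConfig:
    """All knobs of the simulator; defaults are the package's study conditions."""

    n_patients: int = 1
    cells_per_patient: int = 600
    n_genes: int = 2000
    composition: dict = field(
        default_factory=lambda: {"T": 0.10, "B": 0.05, "monocyte": 0.10, "CTC": 0.75}
    )
    population_effect: float = 3.0  # log2, on-lineage program shift
    off_target_effect: float = -12.0  # log2, off-lineage marker suppression (stray-read level)
    patient_effect: float = 3.0  # log2, patient-private program shift in CTCs
    n_patient_genes: int = 30
    nb_mean_baseline: float = 4.0
    nb_dispersion: float = 0.5
    dropout_prob: float = 0.3
    mito_fraction_target: float = 0.05
    cycling_fraction: float = 0.10  # of CTC cells
    cycle_effect: float = 4.0  # log2 boost of the active phase program
    partial_emt_fraction: float = 0.30  # of CTC cells
    emt_effect: float = 6.0  # log2 boost of mes/CSC genes in partial-EMT cells
    cta_detect_prob: float = 0.02  # per CTA gene per CTC cell
    include_immune_signature: bool = True
    # filler-gene baseline means are log2-uniform on [min, max] x baseline/4:
    # real transcriptomes have a long-tailed mean distribution, and gene-set
    # scoring against expression-matched controls is only meaningful when
    # every expression bin is dominated by ordinary unimodal genes
    filler_log2_spread: tuple = (-2.0, 3.0)
    cell_size_log2_sd: float = 0.35  # per-cell library size factor spread
    seed: int = 0

    def validate(self) -> "SyntheticConfig":
        if self.n_patients < 1 or self.cells_per_patient < 1 or self.n_genes < 1:
            raise ValidationError("sizes must be positive")
        total = sum(self.composition.get(p, 0.0) for p in POPULATIONS)
        if total > 1 + 1e-9 or any(v < 0 for v in self.composition.values()):
            raise ValidationError("composition fractions must be valid probabilities summing to <= 1")
        for name in ("dropout_prob", "mito_fraction_target"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValidationError(f"{name} must be in [0, 1)")
        for name in ("cycling_fraction", "partial_emt_fraction", "cta_detect_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.nb_mean_baseline <= 0 or self.nb_dispersion <= 0:
            raise ValidationError("nb_mean_baseline and nb_dispersion must be positive")
        return self


@dataclass
class SyntheticTruth:
    """Planted labels per cell and program memberships per gene."""

    cells: pd.DataFrame  # index cell_id: patient, sample_id, population, cycling, cycle_phase, partial_emt, cta_burden
    genes: pd.DataFrame  # index gene_id: role, base_mean, dispersion
    config: dict


def _build_universe(cfg: SyntheticConfig):
    """Assemble the gene universe and program membership maps."""
    panels = datasets.marker_panels()
    emt = datasets.emt_sets()
    g1s, g2m = datasets.cell_cycle_sets()
    immune_sig = datasets.immune_signature()
    cta = datasets.cta_list()

    programs: dict[str, list[str]] = {
        "T": list(panels["T"]),
        "B": list(panels["B"]),
        "monocyte": list(panels["monocyte"]),
    }
    # pan-immune program: PTPRC plus the signature genes not already in a panel
    panel_genes = {g for p in ("T", "B", "monocyte") for g in panels[p]}
    extras = [g for g in immune_sig if g not in panel_genes] if cfg.include_immune_signature else []
    programs["immune_common"] = list(dict.fromkeys(panels["leukocyte"] + extras))
    # CTC program: lung origin + epithelial (incl. KRT19) + CCND1 + ECM
    ctc_prog = panels["lung"] + emt["epithelial7"] + ["CCND1"] + emt["ecm"]
    programs["CTC"] = list(dict.fromkeys(ctc_prog))
    mes_csc = list(emt["mes_csc"])
    cycle = {"G1S": list(g1s), "G2M": list(g2m)}
    csc_only = [g for g in CSC_BASELINES if g not in mes_csc]

    special: list[tuple[str, str]] = []  # (gene, role)
    for pop in ("T", "B", "monocyte"):
        special += [(g, f"panel:{pop}") for g in programs[pop]]
    special += [(g, "program:immune") for g in programs["immune_common"]]
    special += [(g, "program:CTC") for g in programs["CTC"]]
    special += [(g, "program:mes_csc") for g in mes_csc]
    special += [(g, "marker:csc") for g in csc_only]
    if cfg.cycling_fraction > 0:
        special += [(g, "cycle:G1S") for g in cycle["G1S"]]
        special += [(g, "cycle:G2M") for g in cycle["G2M"] if g != "TOP2A"]
        # TOP2A sits in both the proliferation panel and G2/M; treat as cycle
        special += [("TOP2A", "cycle:G2M")]
    else:
        cycle = {"G1S": [], "G2M": []}
    if cfg.cta_detect_prob > 0:
        special += [(g, "cta") for g in cta]
    else:
        cta = []
    special += [(g, "mito") for g in MT_GENES]

    seen: dict[str, str] = {}
    for g, role in special:
        seen.setdefault(g, role)
    gene_ids = list(seen)
    roles = dict(seen)

    n_patient_total = cfg.n_patients * cfg.n_patient_genes
    n_filler = cfg.n_genes - len(gene_ids) - n_patient_total
    if n_filler < 0:
        raise ValidationError(
            f"n_genes={cfg.n_genes} too small for {len(gene_ids)} program genes "
            f"+ {n_patient_total} patient-program genes"
        )
    patient_genes: dict[str, list[str]] = {}
    k = 0
    for p in range(cfg.n_patients):
        pid = f"P{p + 1}"
        names = [f"GENE{k + j:04d}" for j in range(cfg.n_patient_genes)]
        k += cfg.n_patient_genes
        patient_genes[pid] = names
        for g in names:
            gene_ids.append(g)
            roles[g] = f"patient_program:{pid}"
    for j in range(n_filler):
        g = f"GENE{k + j:04d}"
        gene_ids.append(g)
        roles[g] = "filler"
    return gene_ids, roles, programs, mes_csc, cycle, cta, patient_genes


def generate(config: SyntheticConfig) -> tuple[CountMatrix, SyntheticTruth]:
    """Draw one synthetic cohort; fully reproducible given config.seed."""
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)
    gene_ids, roles, programs, mes_csc, cycle, cta, patient_genes = _build_universe(cfg)
    gi = {g: i for i, g in enumerate(gene_ids)}
    n_genes = len(gene_ids)
    n_cells = cfg.n_patients * cfg.cells_per_patient

    # --- cell labels
    patients = np.repeat([f"P{p + 1}" for p in range(cfg.n_patients)], cfg.cells_per_patient)
    probs = np.array([cfg.composition.get(p, 0.0) for p in POPULATIONS])
    probs = np.append(probs, max(0.0, 1.0 - probs.sum()))  # leftover mass -> CTC
    probs[POPULATIONS.index("CTC")] += probs[-1]
    probs = probs[:-1]
    pops = rng.choice(POPULATIONS, size=n_cells, p=probs / probs.sum())
    is_ctc = pops == "CTC"
    cycling = np.zeros(n_cells, dtype=bool)
    cycling[is_ctc] = rng.random(is_ctc.sum()) < cfg.cycling_fraction
    phase = np.where(cycling, rng.choice(["G1S", "G2M"], size=n_cells), "none")
    phase[~cycling] = "none"
    partial_emt = np.zeros(n_cells, dtype=bool)
    partial_emt[is_ctc] = rng.random(is_ctc.sum()) < cfg.partial_emt_fraction

    # --- mean matrix
    base = np.full(n_genes, cfg.nb_mean_baseline)
    filler_idx = [gi[g] for g in gene_ids if roles[g] == "filler"]
    if filler_idx:
        lo, hi = cfg.filler_log2_spread
        base[filler_idx] = cfg.nb_mean_baseline * 2.0 ** rng.uniform(lo, hi, size=len(filler_idx))
    for g, mu in CSC_BASELINES.items():
        if g in gi and roles[g] == "marker:csc":
            base[gi[g]] = mu
    for g in mes_csc:
        base[gi[g]] = cfg.nb_mean_baseline * 2.0**-4
    for phase_name in ("G1S", "G2M"):
        for g in cycle[phase_name]:
            base[gi[g]] = cfg.nb_mean_baseline * 2.0**-2
    for g in cta:
        base[gi[g]] = 0.0

    mu = np.tile(base[:, None], (1, n_cells))
    on = 2.0**cfg.population_effect
    off = 2.0**cfg.off_target_effect
    immune = ~is_ctc
    for pop in ("T", "B", "monocyte"):
        idx = [gi[g] for g in programs[pop]]
        mu[np.ix_(idx, pops == pop)] *= on
        mu[np.ix_(idx, pops != pop)] *= off
    idx = [gi[g] for g in programs["immune_common"]]
    mu[np.ix_(idx, immune)] *= on
    mu[np.ix_(idx, is_ctc)] *= off
    idx = [gi[g] for g in programs["CTC"]]
    mu[np.ix_(idx, is_ctc)] *= on
    mu[np.ix_(idx, immune)] *= off
    idx = [gi[g] for g in mes_csc]
    mu[np.ix_(idx, partial_emt)] *= 2.0**cfg.emt_effect
    for phase_name in ("G1S", "G2M"):
        idx = [gi[g] for g in cycle[phase_name]]
        if idx:
            mu[np.ix_(idx, phase == phase_name)] *= 2.0**cfg.cycle_effect
    for pid, genes in patient_genes.items():
        idx = [gi[g] for g in genes]
        mu[np.ix_(idx, (patients == pid) & is_ctc)] *= 2.0**cfg.patient_effect

    # per-cell library size factors (log-normal in log2)
    if cfg.cell_size_log2_sd > 0:
        size = 2.0 ** rng.normal(0.0, cfg.cell_size_log2_sd, size=n_cells)
        mu *= size[None, :]

    # mitochondrial load calibrated per cell to the target fraction
    mt_idx = [gi[g] for g in MT_GENES]
    t = cfg.mito_fraction_target
    non_mito_total = np.delete(mu, mt_idx, axis=0).sum(axis=0)
    mu[mt_idx, :] = non_mito_total[None, :] * (t / (1 - t)) / len(MT_GENES)

    # --- counts: NB(mean mu, dispersion theta) thinned by Bernoulli(1 - dropout)
    theta = cfg.nb_dispersion
    p_nb = theta / (theta + mu)
    counts = rng.negative_binomial(theta, p_nb)
    if cfg.dropout_prob > 0:
        keep = rng.random(counts.shape) >= cfg.dropout_prob
        counts = counts * keep

    # --- CTA detections planted post-thinning in CTC cells
    cta_burden = np.zeros(n_cells, dtype=int)
    if cta:
        cta_idx = np.array([gi[g] for g in cta])
        detect = np.zeros((len(cta), n_cells), dtype=bool)
        detect[:, is_ctc] = rng.random((len(cta), is_ctc.sum())) < cfg.cta_detect_prob
        extra = 1 + rng.poisson(1.0, size=detect.shape)
        counts[cta_idx, :] = np.where(detect, extra, 0)
        cta_burden = detect.sum(axis=0).astype(int)

    cell_ids = [f"{p}_C{j:04d}" for j, p in enumerate(patients)]
    meta = pd.DataFrame(
        {"sample_id": patients, "patient_id": patients, "population_label": pops},
        index=pd.Index(cell_ids, name="cell_id"),
    )
    cm = CountMatrix(
        counts=counts.astype(np.int64), gene_ids=gene_ids, cell_ids=cell_ids, cell_meta=meta
    ).validate()
    truth_cells = pd.DataFrame(
        {
            "patient": patients,
            "sample_id": patients,
            "population": pops,
            "cycling": cycling,
            "cycle_phase": phase,
            "partial_emt": partial_emt,
            "cta_burden": cta_burden,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    truth_genes = pd.DataFrame(
        {
            "role": [roles[g] for g in gene_ids],
            "base_mean": base,
            "dispersion": cfg.nb_dispersion,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return cm, SyntheticTruth(cells=truth_cells, genes=truth_genes, config=asdict(cfg))


FIXTURES = {
    "tiny": SyntheticConfig(
        n_patients=2,
        cells_per_patient=15,
        n_genes=60,
        cycling_fraction=0.0,
        cta_detect_prob=0.0,
        include_immune_signature=False,
        n_patient_genes=0,
        seed=0,
    ),
    # one patient at the per-patient scale of a CSF sequencing run
    "default": SyntheticConfig(n_patients=1, cells_per_patient=600, n_genes=2000, seed=0),
    # five-patient cohort
    "cohort": SyntheticConfig(n_patients=5, cells_per_patient=600, n_genes=2000, seed=0),
}


def make_fixture(name: str, seed: int | None = None) -> tuple[CountMatrix, SyntheticTruth]:
    """Named study-scale fixtures: tiny (60x30), default (2000x600), cohort (5x600)."""
    if name not in FIXTURES:
        raise ValidationError(f"unknown fixture {name!r}; choose from {sorted(FIXTURES)}")
    cfg = FIXTURES[name]
    if seed is not None:
        from dataclasses import replace

        cfg = replace(cfg, seed=seed)
    return generate(cfg)
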