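import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from csfctc.diffexpr import (
    PanelCriteria,
    de_two_group,
    patient_signatures,
    select_panel,
    stage_biased_genes,
)
from csfctc.errors import DegenerateInputError, ValidationError

from conftest import small_count_matrix


def brute_force_bh(pvals):
    """Step-up BH written from the definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        val = min(prev, pvals[i] * m / rank_from_top)
        adj[i] = val
        prev = val
    return adj


def nb_groups(rng, mu_a, mu_b, n, theta=2.0, dropout=0.0):
    """Draw two NB groups (genes x cells each)."""
    def draw(mu):
        p = theta / (theta + mu)
        c = rng.negative_binomial(theta, p[:, None], size=(len(mu), n))
        if dropout:
            c = c * (rng.random(c.shape) >= dropout)
        return c
    counts = np.hstack([draw(np.asarray(mu_a, float)), draw(np.asarray(mu_b, float))])
    cm = small_count_matrix(counts, cell_ids=[f"a{i}" for i in range(n)] + [f"b{i}" for i in range(n)])
    return cm, [f"a{i}" for i in range(n)], [f"b{i}" for i in range(n)]


class TestBenjaminiHochberg:
    def test_textbook_example(self):
        adj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])
        np.testing.assert_allclose(brute_force_bh([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_pipeline_bh_matches_brute_force(self, rng):
        """The adjustment used by de_two_group equals the step-up definition."""
        for _ in range(1000):
            p = rng.random(rng.integers(1, 25))
            np.testing.assert_allclose(
                multipletests(p, method="fdr_bh")[1], brute_force_bh(list(p)), atol=1e-12
            )


class TestDeTwoGroup:
    def test_swap_negates_fc_preserves_p(self, rng):
        cm, a, b = nb_groups(rng, np.full(50, 3.0), np.full(50, 1.0), n=10)
        d1 = de_two_group(cm, a, b)
        d2 = de_two_group(cm, b, a)
        np.testing.assert_allclose(d1["log2_fc"], -d2["log2_fc"], atol=1e-12)
        np.testing.assert_allclose(d1["p_raw"], d2["p_raw"], atol=1e-12)

    def test_null_split_calls_nothing(self, rng):
        """Two halves of one homogeneous population: no DEG at p_adj<.05 & |fc|>1."""
        failures = 0
        for _ in range(10):
            mu = np.full(400, 2.0)
            cm, a, b = nb_groups(rng, mu, mu, n=50)
            de = de_two_group(cm, a, b)
            calls = ((de["p_adj"] < 0.05) & (de["log2_fc"].abs() > 1)).sum()
            failures += calls > 0
        assert failures <= 1

    def test_planted_shift_power(self, rng):
        """4x shift, n=100/group, dispersion 0.5 (Var=mu+0.5mu^2): >=95% of
        planted genes recovered with log2FC in [1.5, 2.5] and p_adj < .05."""
        G = 2000
        mu = np.full(G, 2.0)
        pick = rng.choice(G, 60, replace=False)
        up, down = pick[:30], pick[30:]
        mu[pick] = 8.0
        mu_a, mu_b = mu.copy(), mu.copy()
        mu_a[up] *= 4
        mu_b[down] *= 4
        cm, a, b = nb_groups(rng, mu_a, mu_b, n=100)
        de = de_two_group(cm, a, b)
        hu, hd = de.iloc[up], de.iloc[down]
        recovered = ((hu["p_adj"] < 0.05) & hu["log2_fc"].between(1.5, 2.5)).sum()
        recovered += ((hd["p_adj"] < 0.05) & (-hd["log2_fc"]).between(1.5, 2.5)).sum()
        assert recovered / 60 >= 0.95
        null = de.drop(de.index[pick])
        # type-I within the binomial 99% CI of 0.05
        half = 2.576 * np.sqrt(0.05 * 0.95 / len(null))
        assert abs((null["p_raw"] < 0.05).mean() - 0.05) < half

    def test_strict_calls_subset_of_loose_calls(self, rng):
        mu_a = np.concatenate([np.full(30, 8.0), np.full(70, 2.0)])
        mu_b = np.full(100, 2.0)
        cm, a, b = nb_groups(rng, mu_a, mu_b, n=40)
        de = de_two_group(cm, a, b)
        strict = set(de.index[(de["p_adj"] < 0.05) & (de["log2_fc"].abs() > 1)])
        loose = set(de.index[(de["p_raw"] < 0.05) & (de["log2_fc"].abs() > np.log2(1.5))])
        assert strict <= loose

    def test_nb_wald_alternative_recovers_shift(self, rng):
        mu_a = np.concatenate([np.full(20, 16.0), np.full(180, 4.0)])
        mu_b = np.full(200, 4.0)
        cm, a, b = nb_groups(rng, mu_a, mu_b, n=80)
        de = de_two_group(cm, a, b, method="nb_wald")
        assert de.attrs["method"] == "nb_wald"
        assert (de.iloc[:20]["p_adj"] < 0.05).mean() >= 0.9

    def test_input_validation(self, rng):
        cm, a, b = nb_groups(rng, np.full(10, 2.0), np.full(10, 2.0), n=5)
        with pytest.raises(ValidationError):
            de_two_group(cm, a, a[:3] + b[:2])
        with pytest.raises(DegenerateInputError):
            de_two_group(cm, a[:2], b)


class TestPatientSignatures:
    def test_planted_programs_recovered(self):
        from dataclasses import replace

        from csfctc.qc import run_qc
        from csfctc.synthdata import FIXTURES, generate

        cfg = replace(FIXTURES["cohort"], cells_per_patient=150, seed=11)
        cm, truth = generate(cfg)
        cm_qc, _ = run_qc(cm)
        sigs = patient_signatures(cm_qc, cm_qc.cell_meta["patient_id"])
        genes = truth.genes
        planted_all = set(genes.index[genes["role"].str.startswith("patient_program")])
        for pid, sig in sigs.items():
            planted = set(genes.index[genes["role"] == f"patient_program:{pid}"]) & set(
                cm_qc.gene_ids
            )
            assert len(planted & set(sig)) / len(planted) >= 0.90
            cross = set(sig) & (planted_all - planted)
            assert len(cross) <= 0.05 * len(sig)

    def test_single_patient_rejected(self, rng):
        cm, a, b = nb_groups(rng, np.full(20, 2.0), np.full(20, 2.0), n=5)
        with pytest.raises(ValidationError):
            patient_signatures(cm, pd.Series("p0", index=cm.cell_ids))


class TestStageBias:
    def test_planted_signed_recovery(self, rng):
        G = 300
        mu_early = np.full(G, 4.0)
        mu_late = np.full(G, 4.0)
        mu_late[:10] *= 8  # up in late
        mu_early[10:20] *= 8  # up in early
        cm, late_cells, early_cells = nb_groups(rng, mu_late, mu_early, n=60)
        stages = pd.Series(
            ["late"] * 60 + ["early"] * 60, index=late_cells + early_cells
        )
        res = stage_biased_genes(cm, stages, early="early", late="late")
        up_late = {f"g{i}" for i in range(10)}
        up_early = {f"g{i}" for i in range(10, 20)}
        assert len(up_late & set(res["up_in_late"])) >= 9
        assert len(up_early & set(res["up_in_early"])) >= 9
        assert not set(res["up_in_late"]) & up_early

    def test_two_cell_stage_rejected(self, rng):
        cm, a, b = nb_groups(rng, np.full(10, 2.0), np.full(10, 2.0), n=5)
        stages = pd.Series(["late"] * 2 + ["early"] * 8, index=cm.cell_ids)
        with pytest.raises(DegenerateInputError):
            stage_biased_genes(cm, stages, early="early", late="late")


class TestSelectPanel:
    @staticmethod
    def de_table():
        return pd.DataFrame(
            {
                "detect_frac_a": [0.9, 0.8, 0.7, 0.9, 0.4],
                "detect_frac_b": [0.01, 0.02, 0.0, 0.5, 0.0],
                "log2_fc": [3.0, 2.0, 2.5, 4.0, 5.0],
                "p_adj": [1e-4, 1e-3, 1e-2, 1e-5, 1e-6],
                "mean_a": 1.0,
                "mean_b": 0.0,
                "p_raw": 1e-5,
            },
            index=pd.Index(["gA", "gB", "gC", "gD", "gE"], name="gene_id"),
        )

    def test_criteria_and_ranking(self):
        panel = select_panel(self.de_table(), PanelCriteria())
        # gD fails detect_frac_normal, gE fails detect_frac_ctc
        assert list(panel.index) == ["gA", "gB", "gC"]  # ranked by detection gap

    def test_panel_size_one(self):
        panel = select_panel(self.de_table(), PanelCriteria(panel_size=1))
        assert list(panel.index) == ["gA"]

    def test_impossible_criterion_gives_empty_panel(self, caplog):
        with caplog.at_level("WARNING"):
            panel = select_panel(self.de_table(), PanelCriteria(max_p_adj=0.0))
        assert panel.empty

    def test_planted_program_panel_on_synthetic_cohort(self, default_run, default_annotations):
        """CTC-vs-immune DE admits a panel drawn from the planted tumor program."""
        cm_qc = default_run["cm_qc"]
        truth = default_run["truth"].cells.loc[cm_qc.cell_ids]
        ctc = list(truth.index[truth.population == "CTC"])
        immune = list(truth.index[truth.population != "CTC"])
        de = de_two_group(cm_qc, ctc, immune)
        panel = select_panel(de, PanelCriteria())
        program = set(
            default_run["truth"].genes.index[
                default_run["truth"].genes.role.isin(["program:CTC", "program:mes_csc"])
            ]
        )
        # patient-program genes are also CTC-specific in a one-patient cohort
        program |= set(
            default_run["truth"].genes.index[
                default_run["truth"].genes.role.str.startswith("patient_program")
            ]
        )
        assert 15 <= len(panel) <= 20
        assert set(panel.index) <= program
        gaps = (panel["detect_frac_a"] - panel["detect_frac_b"]).to_numpy()
        assert (np.diff(gaps) <= 1e-12).all()
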