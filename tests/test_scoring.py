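import itertools

import numpy as np
import pytest
from scipy.stats import mannwhitneyu, rankdata

from csfctc import normalize
from csfctc.errors import DegenerateInputError, MissingGenesError
from csfctc.io import ExpressionMatrix, GeneSetLibrary
from csfctc.scoring import (
    cycle_scores,
    gsva_like_score,
    module_score,
    preranked_gsea,
    ssgsea_score,
)

from conftest import small_count_matrix


def make_em(values, gene_ids=None, cell_ids=None):
    values = np.asarray(values, dtype=float)
    g, c = values.shape
    return ExpressionMatrix(
        values=values,
        gene_ids=gene_ids or [f"g{i}" for i in range(g)],
        cell_ids=cell_ids or [f"c{i}" for i in range(c)],
        source_total=np.ones(c),
        scale_factor=1.0,
    )


# ---------------------------------------------------------------------------
# brute-force oracles, written independently of the implementation


def naive_ssgsea(values_cell, in_set, exponent):
    """Direct double-loop evaluation of the weighted ECDF difference sum."""
    n = len(values_cell)
    ranks = rankdata(values_cell)
    order = sorted(range(n), key=lambda i: (-ranks[i], i))
    sum_w = sum(ranks[i] ** exponent for i in order if in_set[i])
    n_out = sum(1 for i in range(n) if not in_set[i])
    score, p_in, p_out = 0.0, 0.0, 0.0
    for i in order:
        if in_set[i]:
            p_in += ranks[i] ** exponent / sum_w
        else:
            p_out += 1.0 / n_out
        score += p_in - p_out
    return score


def naive_ks_walk(values_cell, in_set):
    """Enumerate the running sum step by step; return the signed extreme."""
    n = len(values_cell)
    ranks = rankdata(values_cell)
    order = sorted(range(n), key=lambda i: (-ranks[i], i))
    m = sum(in_set)
    walk, best = 0.0, 0.0
    for i in order:
        walk += 1.0 / m if in_set[i] else -1.0 / (n - m)
        if abs(walk) > abs(best):
            best = walk
    return best


def naive_gsea_es(weights, in_set):
    """Running-sum ES with weight exponent 1 over an ordered ranking."""
    n_out = sum(1 for x in in_set if not x)
    denom = sum(abs(w) for w, s in zip(weights, in_set) if s)
    p_hit = p_miss = 0.0
    best = 0.0
    for w, s in zip(weights, in_set):
        if s:
            p_hit += abs(w) / denom
        else:
            p_miss += 1.0 / n_out
        if abs(p_hit - p_miss) > abs(best):
            best = p_hit - p_miss
    return best


# ---------------------------------------------------------------------------
# module score


class TestModuleScore:
    def test_constant_matrix_scores_zero(self):
        em = make_em(np.full((20, 5), 3.0))
        s = module_score(em, ["g0", "g3", "g7"], n_bins=1, n_ctrl=5, seed=0)
        np.testing.assert_allclose(s, 0.0, atol=1e-12)

    def test_hand_computation_single_bin_all_controls(self, rng):
        """6 genes x 2 cells, 1 bin, n_ctrl = pool size: controls are all non-set genes."""
        vals = rng.random((6, 2)) * 3
        em = make_em(vals)
        s = module_score(em, ["g1", "g4"], n_bins=1, n_ctrl=4, seed=0)
        expected = vals[[1, 4]].mean(axis=0) - vals[[0, 2, 3, 5]].mean(axis=0)
        np.testing.assert_allclose(s, expected, atol=1e-10)

    def test_gene_order_invariance(self, default_run):
        em = default_run["em"]
        genes = ["EPCAM", "KRT8", "KRT18", "MUC1"]
        a = module_score(em, genes, seed=5)
        b = module_score(em, genes[::-1], seed=5)
        np.testing.assert_allclose(a, b)

    def test_random_sets_center_on_zero(self, default_run, rng):
        """Random 10-gene sets have mean score ~ 0 across cells (null expectation)."""
        em = default_run["em"]
        means = []
        for _ in range(200):
            genes = [em.gene_ids[i] for i in rng.choice(em.n_genes, 10, replace=False)]
            means.append(module_score(em, genes, seed=0).mean())
        means = np.array(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean()) < 3 * se + 1e-3

    def test_missing_set_raises(self):
        em = make_em(np.ones((5, 2)))
        with pytest.raises(MissingGenesError):
            module_score(em, ["ABSENT1", "ABSENT2"], seed=0)


class TestCycleScores:
    def test_planted_cycling_cells_score_higher(self, cohort_run):
        from csfctc import datasets

        em, truth, cm_qc = cohort_run["em"], cohort_run["truth"], cohort_run["cm_qc"]
        g1s_genes, g2m_genes = datasets.cell_cycle_sets()
        g1s, g2m = cycle_scores(em, g1s_genes, g2m_genes, seed=0)
        t = truth.cells.loc[cm_qc.cell_ids]
        top = np.maximum(g1s, g2m)
        cycling, rest = top[t.cycling.to_numpy()], top[~t.cycling.to_numpy()]
        p = mannwhitneyu(cycling[:200], rest[:200], alternative="greater").pvalue
        assert p < 0.01

    def test_identical_cells_score_zero(self):
        em = make_em(np.tile(np.arange(30, dtype=float)[:, None], (1, 4)))
        g1s, g2m = cycle_scores(em, ["g0", "g5"], ["g10", "g20"], n_bins=1, n_ctrl=10, seed=0)
        # every cell identical => per-cell score equals the same constant; the
        # set and control means differ per set, but cells are indistinguishable
        assert np.ptp(g1s) == pytest.approx(0) and np.ptp(g2m) == pytest.approx(0)

    def test_cell_permutation_equivariance(self, rng):
        vals = rng.random((25, 8))
        em = make_em(vals)
        perm = rng.permutation(8)
        em_p = make_em(vals[:, perm], cell_ids=[f"c{i}" for i in perm])
        a, _ = cycle_scores(em, ["g0", "g1", "g2"], ["g3", "g4"], n_bins=1, n_ctrl=5, seed=3)
        b, _ = cycle_scores(em_p, ["g0", "g1", "g2"], ["g3", "g4"], n_bins=1, n_ctrl=5, seed=3)
        np.testing.assert_allclose(a[perm], b, atol=1e-12)


# ---------------------------------------------------------------------------
# ssGSEA


class TestSsgsea:
    def test_matches_brute_force(self, rng):
        vals = rng.random((10, 3)) * 5
        em = make_em(vals)
        in_set = np.zeros(10, dtype=bool)
        in_set[[1, 4, 7]] = True
        got = ssgsea_score(em, ["g1", "g4", "g7"], exponent=0.25)
        for c in range(3):
            assert got[c] == pytest.approx(naive_ssgsea(vals[:, c], in_set, 0.25), abs=1e-10)

    def test_top_ranks_are_maximal(self, rng):
        """Set genes holding the top |set| ranks maximize the score over permutations."""
        base = np.arange(1.0, 8.0)  # 7 distinct values
        set_mask = [True, True, False, False, False, False, False]
        scores = []
        for perm in itertools.permutations(range(7)):
            vals = base[list(perm)]
            scores.append(naive_ssgsea(vals, set_mask, 0.25))
        em = make_em(np.sort(base)[::-1][:, None].copy())
        top = ssgsea_score(em, ["g0", "g1"], exponent=0.25)[0]
        assert top == pytest.approx(max(scores), abs=1e-10)

    def test_rank_invariance(self, rng):
        vals = rng.random((12, 1))
        em_a = make_em(vals)
        em_b = make_em(np.exp(4 * vals))  # monotone transform preserves ranks
        ga = ssgsea_score(em_a, ["g2", "g5", "g9"])
        gb = ssgsea_score(em_b, ["g2", "g5", "g9"])
        np.testing.assert_allclose(ga, gb, atol=1e-10)

    def test_exchangeable_null_centers_on_zero(self, rng):
        """Random in-set assignment gives empirical mean score ~ 0."""
        n = 40
        scores = []
        for _ in range(500):
            vals = rng.random(n)
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(n, 5, replace=False)] = True
            em = make_em(vals[:, None])
            genes = [f"g{i}" for i in np.flatnonzero(mask)]
            scores.append(ssgsea_score(em, genes, exponent=0.0)[0])
        scores = np.array(scores)
        se = scores.std(ddof=1) / np.sqrt(len(scores))
        assert abs(scores.mean()) < 3 * se

    def test_monotone_in_set_gene_rank(self):
        """Moving a set gene up in rank never decreases the score."""
        vals = np.arange(1.0, 11.0)
        em_low = make_em(vals[:, None])
        # set gene at the bottom vs the same set with that gene at the top
        s_low = ssgsea_score(em_low, ["g0", "g8"])[0]
        s_high = ssgsea_score(em_low, ["g9", "g8"])[0]
        assert s_high >= s_low


# ---------------------------------------------------------------------------
# GSVA-like


class TestGsvaLike:
    def test_matches_brute_force_walk(self, rng):
        vals = rng.random((8, 3)) * 4
        em = make_em(vals)
        lib = GeneSetLibrary(sets={"S": ["g1", "g3", "g6"]})
        sm = gsva_like_score(em, lib)
        raw = sm.parameters["raw"].loc["S"].to_numpy()
        in_set = np.zeros(8, dtype=bool)
        in_set[[1, 3, 6]] = True
        expected = [naive_ks_walk(vals[:, c], in_set) for c in range(3)]
        np.testing.assert_allclose(raw, expected, atol=1e-10)

    def test_extreme_cells_rescale_to_unit_interval(self):
        up = np.concatenate([[10.0, 9.0, 8.0], np.arange(5.0)])  # set genes on top
        down = np.concatenate([[0.1, 0.2, 0.3], np.arange(4.0, 9.0)])  # set at bottom
        mid = np.concatenate([[4.5, 0.2, 8.5], np.arange(1.0, 6.0)])
        em = make_em(np.column_stack([up, down, mid]))
        lib = GeneSetLibrary(sets={"S": ["g0", "g1", "g2"]})
        sm = gsva_like_score(em, lib)
        s = sm.scores.loc["S"]
        assert s.iloc[0] == 1.0 and s.iloc[1] == 0.0
        assert ((sm.scores.to_numpy() >= 0) & (sm.scores.to_numpy() <= 1)).all()

    def test_raw_sign_flips_under_rank_reversal(self, rng):
        vals = rng.random((9, 2))
        lib = GeneSetLibrary(sets={"S": ["g0", "g4"]})
        raw_fwd = gsva_like_score(make_em(vals), lib).parameters["raw"]
        raw_rev = gsva_like_score(make_em(-vals), lib).parameters["raw"]
        # reversal flips which tail the set occupies; signs must oppose
        assert np.all(np.sign(raw_fwd.to_numpy()) == -np.sign(raw_rev.to_numpy()))

    def test_single_cell_degenerate(self):
        em = make_em(np.ones((5, 1)))
        with pytest.raises(DegenerateInputError):
            gsva_like_score(em, GeneSetLibrary(sets={"S": ["g0"]}))


# ---------------------------------------------------------------------------
# preranked GSEA


class TestPrerankedGsea:
    def test_top_concordant_set_significant(self):
        ranking = [(f"g{i}", 5.0 - i * 0.05) for i in range(100)]
        lib = GeneSetLibrary(sets={"TOP": [f"g{i}" for i in range(5)]})
        (res,) = preranked_gsea(ranking, lib, n_perm=1000, seed=0)
        assert res.es > 0
        assert res.p_nominal < 0.05

    def test_es_matches_brute_force(self, rng):
        weights = rng.normal(size=8)
        weights = np.sort(weights)[::-1]
        ranking = [(f"g{i}", w) for i, w in enumerate(weights)]
        lib = GeneSetLibrary(sets={"S": ["g1", "g4", "g6"]})
        (res,) = preranked_gsea(ranking, lib, n_perm=10, seed=0)
        in_set = [g in {"g1", "g4", "g6"} for g, _ in ranking]
        assert res.es == pytest.approx(naive_gsea_es([w for _, w in ranking], in_set), abs=1e-10)

    def test_same_seed_is_bit_identical(self):
        ranking = [(f"g{i}", 3.0 - i * 0.1) for i in range(40)]
        lib = GeneSetLibrary(sets={"A": ["g0", "g5", "g30"], "B": ["g2", "g39"]})
        r1 = preranked_gsea(ranking, lib, n_perm=200, seed=42)
        r2 = preranked_gsea(ranking, lib, n_perm=200, seed=42)
        for a, b in zip(r1, r2):
            assert (a.p_nominal, a.fdr_q, a.nes) == (b.p_nominal, b.fdr_q, b.nes)

    def test_es_bounded_and_p_in_unit_interval(self, rng):
        for _ in range(10):
            n = rng.integers(10, 30)
            weights = np.sort(rng.normal(size=n))[::-1]
            ranking = [(f"g{i}", w) for i, w in enumerate(weights)]
            members = [f"g{i}" for i in rng.choice(n, size=rng.integers(2, n - 1), replace=False)]
            lib = GeneSetLibrary(sets={"S": members})
            (res,) = preranked_gsea(ranking, lib, n_perm=50, seed=int(rng.integers(1e6)))
            assert -1 <= res.es <= 1
            assert 0 < res.p_nominal <= 1
            assert 0 <= res.fdr_q <= 1

    def test_disjoint_set_skipped_with_warning(self, caplog):
        ranking = [("g0", 1.0), ("g1", 0.5), ("g2", -0.5)]
        lib = GeneSetLibrary(sets={"NONE": ["x", "y"], "OK": ["g0", "g2"]})
        with caplog.at_level("WARNING"):
            res = preranked_gsea(ranking, lib, n_perm=20, seed=0)
        assert [r.set_name for r in res] == ["OK"]
        assert "skipped" in caplog.text


def test_immune_score_separates_planted_populations(default_run):
    """Planted immune cells out-score planted CTCs on the immune signature."""
    from csfctc import datasets

    em, truth, cm_qc = default_run["em"], default_run["truth"], default_run["cm_qc"]
    s = ssgsea_score(em, datasets.immune_signature())
    t = truth.cells.loc[cm_qc.cell_ids]
    immune = s[(t.population != "CTC").to_numpy()][:100]
    ctc = s[(t.population == "CTC").to_numpy()][:100]
    assert immune.mean() > ctc.mean()
    assert mannwhitneyu(immune, ctc, alternative="greater").pvalue < 1e-3
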