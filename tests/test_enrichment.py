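import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from icamir.enrichment import (
    DegenerateHypothesisError,
    ScoreVector,
    adjust_pvalues,
    correlation_enrichment,
    foldchange_validation,
    ic_target_enrichment,
    pairwise_cooperativity,
    pathway_enrichment,
    score_enrichment,
    wilcoxon_rank_sum,
)
from icamir.io_formats import ExpressionMatrix, GeneSetCollection
from icamir.seed_targets import TargetMap

from conftest import match_components


class TestWilcoxonRankSum:
    def test_extreme_split_two_sided(self):
        # enumeration: C(6,3)=20 assignments, observed rank sum is the unique
        # minimum -> two-sided p = 2/20
        W, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], "two_sided", mode="exact")
        assert W == 6.0
        assert p == pytest.approx(0.1)

    def test_extreme_split_less(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], "less", mode="exact")
        assert p == pytest.approx(0.05)

    def test_identical_samples_p_near_one(self):
        _, p = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3], "two_sided")
        assert p >= 0.9

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    def test_exact_matches_enumeration_exhaustive(self):
        # every tie-free split with n + m <= 10, oracle = full enumeration
        values = list(range(1, 11))
        for total in range(2, 11):
            pool = values[:total]
            for n in range(1, total):
                for xs in itertools.combinations(pool, n):
                    ys = [v for v in pool if v not in xs]
                    W_obs = sum(sorted(pool).index(v) + 1 for v in xs)
                    sums = [sum(c) for c in itertools.combinations(range(1, total + 1), n)]
                    p_less = sum(s <= W_obs for s in sums) / len(sums)
                    p_greater = sum(s >= W_obs for s in sums) / len(sums)
                    W, p = wilcoxon_rank_sum(list(xs), ys, "two_sided", mode="exact")
                    assert W == W_obs
                    assert p == pytest.approx(min(1.0, 2 * min(p_less, p_greater)))

    def test_exact_matches_scipy(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n, m = rng.integers(2, 6, size=2)
            pooled = rng.permutation(np.arange(1, n + m + 1)).astype(float)
            x, y = pooled[:n], pooled[n:]
            for alt, scipy_alt in [("two_sided", "two-sided"), ("less", "less"),
                                   ("greater", "greater")]:
                _, p = wilcoxon_rank_sum(x, y, alt, mode="exact")
                ref = stats.mannwhitneyu(x, y, alternative=scipy_alt, method="exact")
                assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_normal_approx_close_to_scipy(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        y = rng.normal(0.5, 1, size=60)
        _, p = wilcoxon_rank_sum(x, y, "two_sided", mode="normal")
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_ties_use_midranks(self):
        W, _ = wilcoxon_rank_sum([1.0, 2.0], [2.0, 3.0], "two_sided")
        assert W == 1 + 2.5

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.integers(0, 50), min_size=1, max_size=8),
           st.lists(st.integers(0, 50), min_size=1, max_size=8))
    def test_label_swap_symmetry(self, xs, ys):
        _, p_less = wilcoxon_rank_sum(xs, ys, "less")
        _, p_greater = wilcoxon_rank_sum(ys, xs, "greater")
        assert p_less == pytest.approx(p_greater)
        _, p2a = wilcoxon_rank_sum(xs, ys, "two_sided")
        _, p2b = wilcoxon_rank_sum(ys, xs, "two_sided")
        assert p2a == pytest.approx(p2b)


class TestAdjustPvalues:
    def test_bonferroni_multiplies(self):
        q = adjust_pvalues([0.01, 0.2, 0.5, 0.9, 1.0], "bonferroni")
        assert q[0] == pytest.approx(0.05)
        assert q[-1] == 1.0

    def test_bh_hand_example(self):
        # step-up: q(3)=0.03, q(2)=min(0.03, 0.02*3/2)=0.03, q(1)=min(0.03, 0.01*3)=0.03
        q = adjust_pvalues([0.01, 0.02, 0.03], "bh_fdr")
        np.testing.assert_allclose(q, [0.03, 0.03, 0.03])

    def test_single_p_identity(self):
        assert adjust_pvalues([0.5], "bonferroni")[0] == 0.5
        assert adjust_pvalues([0.5], "bh_fdr")[0] == 0.5

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.2], "bh_fdr")

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_bh_monotone_and_dominated_by_bonferroni(self, ps):
        q_bh = adjust_pvalues(ps, "bh_fdr")
        q_bf = adjust_pvalues(ps, "bonferroni")
        order = np.argsort(ps)
        assert (np.diff(q_bh[order]) >= -1e-12).all()
        assert (q_bf >= q_bh - 1e-12).all()
        assert (q_bh >= np.asarray(ps) - 1e-12).all()

    def test_bh_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(2)
        p = rng.random(200)
        q = adjust_pvalues(p, "bh_fdr")
        _, q_ref, _, _ = multipletests(p, method="fdr_bh")
        np.testing.assert_allclose(q, q_ref, atol=1e-12)


def _score_vector(n=2000, seed=5, shift=-1.0, n_targets=200):
    rng = np.random.default_rng(seed)
    ids = [f"g{i}" for i in range(n)]
    vals = rng.normal(0, 1, size=n)
    tset = set(ids[:n_targets])
    vals[:n_targets] = rng.normal(shift, 0.5, size=n_targets)
    return ScoreVector(ids, vals, "ic_loads", "IC1"), tset


class TestScoreEnrichment:
    def test_planted_negative_shift(self):
        sv, tset = _score_vector()
        res = score_enrichment(sv, tset)
        assert res.p < 1e-10
        assert res.direction == "negative_shift"
        assert res.n_target == 200 and res.n_background == 1800

    def test_null_type_one_error(self):
        rng = np.random.default_rng(6)
        n_rej = 0
        reps = 1000
        ids = [f"g{i}" for i in range(400)]
        for _ in range(reps):
            sv = ScoreVector(ids, rng.normal(size=400), "ic_loads")
            n_rej += score_enrichment(sv, set(ids[:40])).p < 0.05
        assert 0.035 <= n_rej / reps <= 0.065

    def test_target_equals_universe_errors(self):
        sv, _ = _score_vector(n=10, n_targets=2)
        with pytest.raises(DegenerateHypothesisError):
            score_enrichment(sv, set(sv.gene_ids))

    def test_empty_target_errors(self):
        sv, _ = _score_vector(n=10, n_targets=2)
        with pytest.raises(DegenerateHypothesisError):
            score_enrichment(sv, set())

    def test_monotone_transform_invariance(self):
        sv, tset = _score_vector(n=300, n_targets=30, shift=-0.5)
        p1 = score_enrichment(sv, tset).p
        sv2 = ScoreVector(sv.gene_ids, np.exp(sv.values) * 3 + 1, sv.kind)
        p2 = score_enrichment(sv2, tset).p
        assert p1 == pytest.approx(p2)


class TestICTargetEnrichment:
    def test_planted_mirnas_detected(self, small_bundle, small_decomp, small_ranking, small_targets):
        sig = [r.component for r in small_ranking if r.significant]
        table, summary = ic_target_enrichment(small_decomp, small_targets, sig)
        truth = small_bundle.truth
        q = summary.set_index("mirna_id")["q_min"]
        for m in truth.mirna_ids:
            assert q[m] < 0.1
        # planted miRNAs rank above every decoy
        assert q[truth.mirna_ids].max() < q[truth.decoy_ids].min()

    def test_best_ic_matches_planted_program(self, small_bundle, small_decomp,
                                             small_ranking, small_targets):
        truth = small_bundle.truth
        matching, _ = match_components(truth.C_modified, small_decomp.loads)
        sig = [r.component for r in small_ranking if r.significant]
        _, summary = ic_target_enrichment(small_decomp, small_targets, sig)
        best = summary.set_index("mirna_id")["best_ic"]
        for m in truth.mirna_ids:
            expected = f"IC{matching[truth.program_assignment[m]] + 1}"
            assert best[m] == expected

    def test_bh_identity_single_test(self, small_decomp, small_targets):
        m = small_targets.mirna_ids[0]
        table, _ = ic_target_enrichment(small_decomp, small_targets, [0], mirna_ids=[m])
        assert len(table) == 1
        assert table["q"].iloc[0] == pytest.approx(table["p"].iloc[0])

    def test_requires_significant_ics(self, small_decomp, small_targets):
        with pytest.raises(ValueError, match="rank_components"):
            ic_target_enrichment(small_decomp, small_targets, [])


class TestCorrelationEnrichment:
    def test_planted_anticorrelation(self):
        rng = np.random.default_rng(9)
        S, n_targets, n_genes = 12, 50, 1000
        profile = rng.normal(size=S)
        X = rng.normal(size=(n_genes, S))
        X[:n_targets] = -profile + rng.normal(0, 0.05, size=(n_targets, S))
        ids = [f"g{i}" for i in range(n_genes)]
        mat = ExpressionMatrix(ids, [f"s{j}" for j in range(S)], X)
        res = correlation_enrichment(mat, profile, set(ids[:n_targets]))
        assert res.p < 1e-8
        assert res.direction == "negative_shift"

    def test_constant_profile_errors(self):
        mat = ExpressionMatrix(["g1", "g2"], ["s1", "s2", "s3"],
                               np.arange(6.0).reshape(2, 3))
        with pytest.raises(ValueError, match="constant"):
            correlation_enrichment(mat, np.ones(3), {"g1"})

    def test_zero_variance_genes_dropped(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(5, 6))
        X[2] = 1.0  # flat gene
        ids = [f"g{i}" for i in range(5)]
        mat = ExpressionMatrix(ids, [f"s{j}" for j in range(6)], X)
        res = correlation_enrichment(mat, rng.normal(size=6), {"g0", "g1"})
        assert res.n_target + res.n_background == 4

    def test_null_p_uniform(self):
        rng = np.random.default_rng(11)
        reps, hits = 300, 0
        for _ in range(reps):
            X = rng.normal(size=(200, 10))
            ids = [f"g{i}" for i in range(200)]
            mat = ExpressionMatrix(ids, [f"s{j}" for j in range(10)], X)
            res = correlation_enrichment(mat, rng.normal(size=10), set(ids[:20]))
            hits += res.p < 0.05
        assert 0.02 <= hits / reps <= 0.09


class TestPairwiseCooperativity:
    def _decomp(self, loads, n=1):
        from icamir.ica_core import ICADecomposition
        G = loads.shape[0]
        return ICADecomposition(
            gene_ids=[f"g{i}" for i in range(G)], sample_ids=["s1", "s2"],
            loads=loads, mixes=np.zeros((loads.shape[1], 2)),
            n_components=loads.shape[1], converged=np.ones(loads.shape[1], bool),
            negentropies=np.zeros(loads.shape[1]), rng_seed=0,
        )

    def test_planted_pair_significant(self):
        rng = np.random.default_rng(12)
        G = 1000
        loads = rng.normal(size=(G, 1))
        common = set(range(100))
        for i in common:
            loads[i, 0] -= 2.0
        d = self._decomp(loads)
        genes = set(d.gene_ids)
        targets = TargetMap(
            ["m1", "m2"], genes,
            {"m1": {f"g{i}" for i in range(150)}, "m2": {f"g{i}" for i in range(100)} | {f"g{i}" for i in range(900, 950)}},
            {},
        )
        targets.site_counts = {(m, g): 1 for m, gs in targets.targets.items() for g in gs}
        df = pairwise_cooperativity(d, targets, 0)
        assert len(df) == 1
        assert df["q"].iloc[0] < 0.05
        assert df["direction"].iloc[0] == "negative_shift"

    def test_pair_counting_contract(self, small_decomp, small_targets):
        df = pairwise_cooperativity(small_decomp, small_targets, 0)
        n_mirnas = len(small_targets.mirna_ids)
        assert df.attrs["n_pairs_tested"] + df.attrs["n_pairs_skipped"] == n_mirnas * (n_mirnas - 1) // 2
        if len(df):
            # Bonferroni multiplier = number of tested pairs
            assert df["q"].iloc[0] == pytest.approx(
                min(1.0, df["p"].iloc[0] * df.attrs["n_pairs_tested"]))

    def test_disjoint_pair_skipped(self):
        rng = np.random.default_rng(13)
        loads = rng.normal(size=(50, 1))
        d = self._decomp(loads)
        targets = TargetMap(["m1", "m2"], set(d.gene_ids),
                            {"m1": {"g0", "g1"}, "m2": {"g10", "g11"}}, {})
        targets.site_counts = {(m, g): 1 for m, gs in targets.targets.items() for g in gs}
        df = pairwise_cooperativity(d, targets, 0)
        assert len(df) == 0
        assert df.attrs["n_pairs_skipped"] == 1

    def test_invalid_component(self, small_decomp, small_targets):
        with pytest.raises(ValueError):
            pairwise_cooperativity(small_decomp, small_targets, 999)


class TestPathwayEnrichment:
    def test_planted_pathway_detected(self, small_bundle, small_decomp,
                                      small_ranking, small_targets):
        truth = small_bundle.truth
        matching, _ = match_components(truth.C_modified, small_decomp.loads)
        sig = [r.component for r in small_ranking if r.significant]
        df = pathway_enrichment(small_decomp, small_targets, small_bundle.genesets, ics=sig)
        gpos = {g: i for i, g in enumerate(truth.gene_ids)}
        for name, info in truth.pathway_assignments.items():
            ic = matching[info["program"]]
            row = df[(df["pathway"] == name) & (df["ic"] == f"IC{ic + 1}")]
            assert len(row) == 1
            assert row["q"].iloc[0] < 0.05
            # expected sign: truth median modulated by the matched component's
            # orientation relative to the true program
            est = small_decomp.loads[[gpos[g] for g in truth.gene_ids], ic]
            orient = np.sign(np.corrcoef(truth.C_modified[:, info["program"]], est)[0, 1])
            expected = "positive" if orient * info["true_median_load"] > 0 else "negative"
            assert row["sign"].iloc[0] == expected

    def test_small_pathways_skipped(self, small_decomp, small_targets):
        gs = GeneSetCollection({"tiny": ("d", {"g0001"})})
        df = pathway_enrichment(small_decomp, small_targets, gs, ics=[0])
        assert len(df) == 0

    def test_threshold_only_affects_drivers(self, small_bundle, small_decomp, small_targets):
        df1 = pathway_enrichment(small_decomp, small_targets, small_bundle.genesets,
                                 load_threshold=2.0, ics=[0])
        df2 = pathway_enrichment(small_decomp, small_targets, small_bundle.genesets,
                                 load_threshold=np.inf, ics=[0])
        np.testing.assert_allclose(df1["p"], df2["p"])
        assert (df2["drivers"].astype(str).str.len() == 0).all()

    def test_empty_universe_errors(self, small_decomp):
        targets = TargetMap(["m1"], {"zzz"}, {"m1": {"zzz"}}, {("m1", "zzz"): 1})
        with pytest.raises(DegenerateHypothesisError):
            pathway_enrichment(small_decomp, targets, GeneSetCollection({"p": ("d", {"zzz"})}))


class TestFoldchangeValidation:
    def test_planted_upshift(self, small_targets, small_bundle):
        rng = np.random.default_rng(14)
        genes = sorted(small_targets.gene_universe)
        vals = rng.normal(0, 0.3, size=len(genes))
        m = small_targets.mirna_ids[0]
        tset = small_targets.targets[m]
        for i, g in enumerate(genes):
            if g in tset:
                vals[i] += 0.5
        sv = ScoreVector(genes, vals, "fold_change", "cytokine")
        df = foldchange_validation(sv, small_targets)
        row = df[df["mirna_id"] == m]
        assert row["q"].iloc[0] < 0.05
        assert row["direction"].iloc[0] == "positive_shift"

    def test_flat_foldchanges_null(self, small_targets):
        rng = np.random.default_rng(15)
        genes = sorted(small_targets.gene_universe)
        n_sig = 0
        reps = 40
        for _ in range(reps):
            sv = ScoreVector(genes, rng.normal(size=len(genes)), "fold_change")
            df = foldchange_validation(sv, small_targets)
            n_sig += int((df["q"] < 0.05).any())
        assert n_sig / reps <= 0.2

    def test_degenerate_universe(self):
        targets = TargetMap(["m1"], {"g1"}, {"m1": {"g1"}}, {("m1", "g1"): 1})
        sv = ScoreVector(["g1"], [0.5], "fold_change")
        with pytest.raises(DegenerateHypothesisError):
            foldchange_validation(sv, targets)
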