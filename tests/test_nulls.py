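import numpy as np
import pandas as pd
import pytest

from csea import (
    CellPartition,
    CseaError,
    CseaParams,
    EnrichmentResult,
    ExpressionMatrix,
    GaussianMixtureSpec,
    GeneSignature,
    MatchedGenesetSpec,
    ScoreVector,
    benjamini_hochberg,
    geneset_null_pvalue,
    match_sensitivity,
    matched_geneset,
    permutation_pvalue,
    screen_signatures,
    simulate_gaussian,
)
from csea.nulls import _candidate_pools


def _expr_with_means(means, n_cells=10, seed=0):
    """Cells x genes matrix whose per-gene means are (approximately) given."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i:03d}" for i in range(len(means))]
    cells = [f"c{i:03d}" for i in range(n_cells)]
    noise = rng.normal(0, 1e-6, size=(n_cells, len(means)))
    noise -= noise.mean(axis=0)  # exact column means
    values = np.asarray(means)[None, :] + noise
    values += rng.normal(0, 1e-3, size=(n_cells, 1))  # per-cell variation
    return ExpressionMatrix(values, cells, genes)


class TestPermutationPvalue:
    def test_seeded_and_reproducible(self, six_cell, default_params):
        scores, part = six_cell
        p1 = permutation_pvalue(scores, part, default_params).p_value
        p2 = permutation_pvalue(scores, part, default_params).p_value
        assert p1 == p2

    def test_strong_signal_gives_raw_zero(self, default_params):
        sim = simulate_gaussian(
            GaussianMixtureSpec(n_per_group=300, mean2=10.0, outlier_frac=0.5, rng_seed=0)
        )
        res = permutation_pvalue(sim.scores, sim.partition, default_params)
        assert res.p_value == 0.0

    def test_pseudo_count_bounds_pvalue_away_from_zero(self, default_params):
        from dataclasses import replace

        sim = simulate_gaussian(
            GaussianMixtureSpec(n_per_group=300, mean2=10.0, outlier_frac=0.5, rng_seed=0)
        )
        params = replace(default_params, pseudo_count=True)
        res = permutation_pvalue(sim.scores, sim.partition, params)
        assert res.p_value == pytest.approx(1 / (params.n_permutations + 1))

    def test_tied_scores_make_observed_es_exchangeable(self):
        """With identical scores the observed ES is just another draw from
        the permutation distribution, so p-values stay well away from 0."""
        ids = [f"c{i:02d}" for i in range(30)]
        sv = ScoreVector(pd.Series(1.0, index=ids))
        pvals = []
        for s in range(20):
            rng = np.random.default_rng(s)
            labels = pd.Series(
                rng.permutation(["in"] * 10 + ["out"] * 20), index=ids
            )
            part = CellPartition(labels, "in")
            pvals.append(
                permutation_pvalue(
                    sv, part, CseaParams(weight_exponent=0.0, rng_seed=s)
                ).p_value
            )
        assert np.mean(pvals) > 0.2  # roughly uniform, certainly not all tiny

    def test_null_pvalues_are_uniform(self):
        """Exchangeable null: labels independent of scores."""
        from scipy.stats import kstest

        pvals = []
        params = CseaParams(n_permutations=50)
        for rep in range(200):
            rng = np.random.default_rng(rep)
            ids = [f"c{i:03d}" for i in range(60)]
            sv = ScoreVector(pd.Series(rng.normal(size=60), index=ids))
            labels = pd.Series(["in"] * 20 + ["out"] * 40, index=ids)
            part = CellPartition(labels, "in")
            from dataclasses import replace

            pvals.append(permutation_pvalue(sv, part, replace(params, rng_seed=rep)).p_value)
        stat = kstest(pvals, "uniform").statistic
        assert stat <= 1 / 50 + 1.36 / np.sqrt(200)


class TestMatchedGeneset:
    def test_deterministic_when_pool_size_one_with_unique_twins(self):
        # genes 0..4 are the signature; genes 5..9 duplicate their means
        means = [1.0, 2.0, 3.0, 4.0, 5.0, 1.0, 2.0, 3.0, 4.0, 5.0]
        expr = _expr_with_means(means)
        sig = GeneSignature("s", positive=frozenset({"g000", "g001"}), negative=frozenset({"g002"}))
        spec = MatchedGenesetSpec(pool_size=1, rng_seed=0)
        got = matched_geneset(sig, expr, spec)
        assert got.positive == {"g005", "g006"}
        assert got.negative == {"g007"}

    def test_disjoint_from_signature_and_size_preserving(self):
        rng = np.random.default_rng(1)
        expr = _expr_with_means(rng.uniform(0, 5, size=60), n_cells=15, seed=1)
        sig = GeneSignature(
            "s",
            positive=frozenset({"g000", "g010", "g020"}),
            negative=frozenset({"g030", "g040"}),
        )
        spec = MatchedGenesetSpec(pool_size=5, rng_seed=3)
        got = matched_geneset(sig, expr, spec)
        assert not (got.genes & sig.genes)
        assert len(got.positive) == 3 and len(got.negative) == 2

    def test_pools_match_independent_full_sort_oracle(self):
        rng = np.random.default_rng(2)
        means = rng.uniform(0, 10, size=40)
        expr = _expr_with_means(means, n_cells=12, seed=2)
        sig = GeneSignature("s", positive=frozenset({"g003", "g017"}))
        spec = MatchedGenesetSpec(pool_size=4, rng_seed=0)
        pools = _candidate_pools(sig, expr, spec)
        col_means = expr.dense().mean(axis=0)
        by_gene = dict(zip(expr.gene_ids, col_means))
        for g, pool in pools.items():
            others = sorted(
                (gid for gid in expr.gene_ids if gid not in sig.genes),
                key=lambda gid: (abs(by_gene[gid] - by_gene[g]), gid),
            )
            assert list(pool) == others[:4]
            # every pool member is at least as close in mean as any outsider
            worst_in_pool = max(abs(by_gene[c] - by_gene[g]) for c in pool)
            best_outside = min(
                abs(by_gene[o] - by_gene[g]) for o in others[4:]
            )
            assert worst_in_pool <= best_outside + 1e-12

    def test_pool_exhaustion_raises(self):
        # two signature genes share the single nearest candidate
        means = [1.0, 1.0, 1.0, 50.0]
        expr = _expr_with_means(means, n_cells=8)
        sig = GeneSignature("s", positive=frozenset({"g000", "g001"}))
        with pytest.raises(CseaError, match="pool"):
            matched_geneset(sig, expr, MatchedGenesetSpec(pool_size=1, rng_seed=0))

    def test_too_few_candidates_raises(self):
        expr = _expr_with_means([1.0, 2.0, 3.0], n_cells=6)
        sig = GeneSignature("s", positive=frozenset({"g000", "g001"}))
        with pytest.raises(CseaError, match="candidate"):
            matched_geneset(sig, expr, MatchedGenesetSpec(pool_size=5))


class TestGenesetNull:
    @pytest.fixture
    def labelled_expr(self):
        rng = np.random.default_rng(5)
        n_cells, n_genes = 80, 120
        values = rng.normal(2, 1, size=(n_cells, n_genes))
        cells = [f"c{i:03d}" for i in range(n_cells)]
        genes = [f"g{i:03d}" for i in range(n_genes)]
        # signature genes 0..9 are shifted up in the first 20 cells
        values[:20, :10] += 3.0
        expr = ExpressionMatrix(values, cells, genes)
        labels = pd.Series(["case"] * 20 + ["ctrl"] * 60, index=cells)
        part = CellPartition(labels, "case")
        sig = GeneSignature("hot", positive=frozenset(genes[:10]))
        return expr, part, sig

    def test_strong_signature_beats_all_controls(self, labelled_expr, default_params):
        expr, part, sig = labelled_expr
        p = geneset_null_pvalue(
            expr=expr, sig=sig, part=part, params=default_params,
            spec=MatchedGenesetSpec(pool_size=10, rng_seed=1, n_sets=50),
        )
        assert p == 0.0

    def test_single_set_reduces_to_binary_comparison(self, labelled_expr, default_params):
        expr, part, sig = labelled_expr
        p = geneset_null_pvalue(
            expr=expr, sig=sig, part=part, params=default_params,
            spec=MatchedGenesetSpec(pool_size=10, rng_seed=2, n_sets=1),
        )
        assert p in (0.0, 1.0)


def test_benjamini_hochberg_textbook_example():
    adj = benjamini_hochberg([0.01, 0.02, 0.04, 0.5])
    np.testing.assert_allclose(adj, [0.04, 0.04, 0.04 * 4 / 3, 0.5], atol=1e-12)


def _result(name, p, le_size, subset_size=1):
    le = [f"x{i}" for i in range(le_size)]
    return EnrichmentResult(
        es=0.5, argmax_rank=le_size, leading_edge=le,
        leading_edge_subset=le[:subset_size], n_r=1.0, p_value=p, signature_name=name,
    )


class TestScreening:
    def test_single_signature_retained(self):
        table = screen_signatures([(_result("s", 0.01, 300), _result("s_ctrl", 0.5, 10))])
        assert bool(table.retained.iloc[0])

    def test_leading_edge_boundary_is_strict(self):
        table = screen_signatures([(_result("s", 0.01, 1000), _result("s_ctrl", 0.5, 10))])
        assert not bool(table.retained.iloc[0])
        table = screen_signatures([(_result("s", 0.01, 999), _result("s_ctrl", 0.5, 10))])
        assert bool(table.retained.iloc[0])

    def test_significant_control_rejects(self):
        table = screen_signatures([(_result("s", 0.01, 300), _result("s_ctrl", 0.01, 10))])
        assert not bool(table.retained.iloc[0])

    def test_lowering_true_pvalue_never_drops_a_retained_signature(self):
        pairs = [
            (_result("a", 0.01, 100), _result("a_c", 0.8, 10)),
            (_result("b", 0.04, 200), _result("b_c", 0.9, 10)),
            (_result("c", 0.7, 50), _result("c_c", 0.6, 10)),
        ]
        before = screen_signatures(pairs)
        pairs2 = [
            (_result("a", 0.001, 100), _result("a_c", 0.8, 10)),
            (_result("b", 0.04, 200), _result("b_c", 0.9, 10)),
            (_result("c", 0.7, 50), _result("c_c", 0.6, 10)),
        ]
        after = screen_signatures(pairs2)
        retained_before = set(before[before.retained].signature)
        retained_after = set(after[after.retained].signature)
        assert retained_before <= retained_after


@pytest.fixture(scope="module")
def count_sim():
    # count data: a gene's mean determines its z-score behaviour
    # (low-mean genes are mostly zeros), so how well a control set
    # matches the signature's expression profile matters
    from csea import CountSimSpec, simulate_counts

    return simulate_counts(
        CountSimSpec(
            n_per_group=100, n_genes=400, frac_de_genes=0.025, rng_seed=3,
            mixture=GaussianMixtureSpec(n_per_group=100, mean2=7.0, outlier_frac=0.2),
        )
    )


class TestMatchSensitivity:
    def test_tight_matching_has_lowest_variance_unmatched_highest(self, count_sim):
        table = match_sensitivity(
            count_sim.signature, count_sim.expr, count_sim.partition,
            pool_sizes=[1, 20, "unmatched"], n_draws=100, rng_seed=0,
        )
        sd = dict(zip(table.pool_size, table.es_sd))
        assert sd[1] <= sd[20] <= sd["unmatched"]

    def test_identically_distributed_genes_make_pool_size_irrelevant(self):
        # exchangeable universe: every gene has the same distribution, so
        # matched and unmatched control ES distributions coincide up to
        # sampling error
        rng = np.random.default_rng(7)
        n_cells, n_genes = 100, 120
        values = rng.normal(1.0, 1.0, size=(n_cells, n_genes))
        cells = [f"c{i:03d}" for i in range(n_cells)]
        genes = [f"g{i:03d}" for i in range(n_genes)]
        expr = ExpressionMatrix(values, cells, genes)
        part = CellPartition(
            pd.Series(["case"] * 30 + ["ctrl"] * 70, index=cells), "case"
        )
        sig = GeneSignature("s", positive=frozenset(genes[:8]))
        table = match_sensitivity(
            sig, expr, part, pool_sizes=[20, "unmatched"], n_draws=100, rng_seed=1
        )
        m = dict(zip(table.pool_size, table.es_mean))
        s = dict(zip(table.pool_size, table.es_sd))
        pooled_se = np.sqrt((s[20] ** 2 + s["unmatched"] ** 2) / 100)
        assert abs(m[20] - m["unmatched"]) < 4 * pooled_se + 0.01

    def test_output_has_one_row_per_pool_size(self, count_sim):
        table = match_sensitivity(
            count_sim.signature, count_sim.expr, count_sim.partition,
            pool_sizes=[2, 5, 20], n_draws=20, rng_seed=0,
        )
        assert len(table) == 3
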