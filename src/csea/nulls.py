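"""Null models and multiple-testing control for the enrichment test.

Two complementary nulls are provided. The label permutation null shuffles
the condition labels over cells (preserving group sizes) and compares the
observed enrichment score against the shuffled ones. The matched-geneset
null keeps the labels fixed and replaces the signature by random control
gene sets matched in size and per-gene mean expression, testing whether
the enrichment is specific to the signature's genes rather than to any
gene set with that expression profile.

P-value convention: p is the fraction of null enrichment scores that are
greater than or equal to the observed one; with the add-one (pseudo-count)
option, p = (k + 1) / (n + 1) so p is never exactly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .core import enrichment_score, es_batch, rank_cells, _hit_weights
from .scoring import score_signatures
from .types import (
    CellPartition,
    CseaError,
    CseaParams,
    EnrichmentResult,
    ExpressionMatrix,
    GeneSignature,
    ScoreVector,
    ValidationError,
)

log = logging.getLogger(__name__)


@dataclass
class MatchedGenesetSpec:
    """How to build expression-matched random control gene sets.

    For every signature gene, its candidate pool is the ``pool_size`` genes
    with the closest mean expression (across all cells of the normalized
    log matrix); one candidate is sampled uniformly, without replacement
    across the control set. ``n_sets`` is 1 for screening and 1000 for the
    geneset-null validation.
    """

    pool_size: int = 20
    exclude_signature_genes: bool = True
    rng_seed: int = 0
    n_sets: int = 1

    def __post_init__(self) -> None:
        if self.pool_size < 1:
            raise ValidationError("pool_size must be >= 1")
        if self.n_sets < 1:
            raise ValidationError("n_sets must be >= 1")


def _pvalue(k: int, n: int, pseudo_count: bool) -> float:
    if pseudo_count:
        return (k + 1) / (n + 1)
    return k / n


def permutation_pvalue(
    scores: ScoreVector, part: CellPartition, params: CseaParams
) -> EnrichmentResult:
    """Enrichment result with a label-permutation p-value attached.

    Condition labels are shuffled uniformly at random ``n_permutations``
    times, preserving N_H; the ranking itself does not depend on labels
    and is computed once.
    """
    ranked = rank_cells(scores, params.direction)
    obs = enrichment_score(ranked, scores, part, params.weight_exponent)
    rng = np.random.default_rng(params.rng_seed)
    r = scores.scores.reindex(ranked).to_numpy()
    w = _hit_weights(r, params.weight_exponent)
    in_set = part.in_set(ranked)
    perms = rng.permuted(
        np.tile(in_set, (params.n_permutations, 1)), axis=1
    )
    es_null = es_batch(w, perms)
    k = int((es_null >= obs.es).sum())
    obs.p_value = _pvalue(k, params.n_permutations, params.pseudo_count)
    return obs


def _candidate_pools(
    sig: GeneSignature, expr: ExpressionMatrix, spec: MatchedGenesetSpec
) -> dict:
    """Per signature gene: the pool_size nearest-mean candidate gene ids."""
    from scipy import sparse

    X = expr.values
    means = (
        np.asarray(X.mean(axis=0)).ravel()
        if sparse.issparse(X)
        else X.mean(axis=0)
    )
    gene_ids = expr.gene_ids
    idx = pd.Index(gene_ids)
    present = [g for g in sorted(sig.genes) if g in idx]
    if not present:
        raise ValidationError(f"no gene of signature {sig.name!r} is in the matrix")
    candidate_mask = np.ones(gene_ids.size, dtype=bool)
    if spec.exclude_signature_genes:
        candidate_mask[idx.get_indexer(present)] = False
    n_candidates = int(candidate_mask.sum())
    if n_candidates < spec.pool_size:
        raise CseaError(
            f"only {n_candidates} candidate genes for pool_size={spec.pool_size}; "
            "use a larger gene universe or a smaller pool"
        )
    cand_ids = gene_ids[candidate_mask]
    cand_means = means[candidate_mask]
    pools = {}
    for g in present:
        target = means[idx.get_loc(g)]
        diffs = np.abs(cand_means - target)
        order = np.lexsort((cand_ids, diffs))[: spec.pool_size]
        pools[g] = cand_ids[order]
    return pools


def _draw_matched(
    sig: GeneSignature, pools: dict, rng: np.random.Generator, name: str
) -> GeneSignature:
    chosen: set = set()
    out_pos, out_neg = [], []
    for subset, out in ((sig.positive, out_pos), (sig.negative, out_neg)):
        for g in sorted(subset):
            if g not in pools:
                continue  # gene absent from the matrix
            avail = [c for c in pools[g] if c not in chosen]
            if not avail:
                raise CseaError(
                    f"candidate pool exhausted for gene {g!r}; use a larger "
                    "gene universe or a smaller pool_size"
                )
            pick = avail[int(rng.integers(len(avail)))]
            chosen.add(pick)
            out.append(pick)
    return GeneSignature(name, positive=frozenset(out_pos), negative=frozenset(out_neg))


def matched_geneset(
    sig: GeneSignature,
    expr: ExpressionMatrix,
    spec: MatchedGenesetSpec,
    rng: "np.random.Generator | None" = None,
) -> GeneSignature:
    """One random control gene set matched in size and mean expression.

    Sampling is without replacement across the output set so the control
    has exactly as many (matrix-present) genes as the signature, with the
    positive/negative structure mirrored.
    """
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    pools = _candidate_pools(sig, expr, spec)
    return _draw_matched(sig, pools, rng, f"{sig.name}__matched")


def geneset_null_pvalue(
    sig: GeneSignature,
    expr: ExpressionMatrix,
    part: CellPartition,
    params: CseaParams,
    spec: MatchedGenesetSpec,
) -> float:
    """P-value of the observed ES against ``spec.n_sets`` matched controls."""
    rng = np.random.default_rng(spec.rng_seed)
    pools = _candidate_pools(sig, expr, spec)
    controls = [
        _draw_matched(sig, pools, rng, f"{sig.name}__matched{i}")
        for i in range(spec.n_sets)
    ]
    table = score_signatures(expr, [sig] + controls)
    true_scores = ScoreVector(table.iloc[:, 0], signature_name=sig.name)
    ranked = rank_cells(true_scores, params.direction)
    es_true = enrichment_score(ranked, true_scores, part, params.weight_exponent).es
    k = 0
    for ctrl in controls:
        sv = ScoreVector(table[ctrl.name], signature_name=ctrl.name)
        rk = rank_cells(sv, params.direction)
        if enrichment_score(rk, sv, part, params.weight_exponent).es >= es_true:
            k += 1
    return _pvalue(k, spec.n_sets, params.pseudo_count)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH-adjusted p-values (delegates to statsmodels)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def screen_signatures(
    pairs,
    alpha: float = 0.05,
    max_leading_edge: int = 1000,
) -> pd.DataFrame:
    """Apply the three-part screening filter over many signatures.

    ``pairs`` is a sequence of (true, control) :class:`EnrichmentResult`
    objects per signature, each carrying a p-value. BH correction is
    applied across signatures separately within the true and the control
    p-value families; a signature is retained when the corrected true p is
    < alpha, the corrected control p is > alpha, and the leading edge is
    strictly smaller than ``max_leading_edge`` cells.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValidationError("screen_signatures needs at least one signature")
    for true_r, ctrl_r in pairs:
        if true_r.p_value is None or ctrl_r.p_value is None:
            raise ValidationError("both true and control results need p-values")
    q_true = benjamini_hochberg([t.p_value for t, _ in pairs])
    q_ctrl = benjamini_hochberg([c.p_value for _, c in pairs])
    rows = []
    for (true_r, ctrl_r), qt, qc in zip(pairs, q_true, q_ctrl):
        true_r.corrected_p = float(qt)
        ctrl_r.corrected_p = float(qc)
        le = len(true_r.leading_edge)
        rows.append(
            {
                "signature": true_r.signature_name,
                "set": true_r.set_label,
                "es": true_r.es,
                "p_value": true_r.p_value,
                "corrected_p": float(qt),
                "control_p_value": ctrl_r.p_value,
                "control_corrected_p": float(qc),
                "leading_edge_size": le,
                "leading_edge_subset_size": len(true_r.leading_edge_subset),
                "retained": bool(qt < alpha and qc > alpha and le < max_leading_edge),
            }
        )
    return pd.DataFrame(rows)


def match_sensitivity(
    sig: GeneSignature,
    expr: ExpressionMatrix,
    part: CellPartition,
    pool_sizes,
    params: "CseaParams | None" = None,
    n_draws: int = 100,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Distribution of control-set ES at varying match tightness.

    ``pool_sizes`` is a list of integers plus optionally the string
    ``"unmatched"``, which draws control genes uniformly from the whole
    non-signature universe. Tighter pools (smaller k) yield less variable
    control ES; fully random sets are the most variable, which is why some
    degree of expression matching is required for a usable control.
    """
    if params is None:
        params = CseaParams()
    idx = pd.Index(expr.gene_ids)
    present_pos = sorted(sig.positive & set(idx))
    present_neg = sorted(sig.negative & set(idx))
    universe = np.asarray(sorted(set(expr.gene_ids) - sig.genes), dtype=str)
    rows = []
    for level_i, level in enumerate(pool_sizes):
        rng = np.random.default_rng(np.random.SeedSequence([rng_seed, level_i]))
        es_values = np.empty(n_draws)
        if level == "unmatched":
            n_needed = len(present_pos) + len(present_neg)
            if universe.size < n_needed:
                raise CseaError("gene universe too small for unmatched draws")
            controls = []
            for i in range(n_draws):
                picked = rng.choice(universe, size=n_needed, replace=False)
                controls.append(
                    GeneSignature(
                        f"{sig.name}__unmatched{i}",
                        positive=frozenset(picked[: len(present_pos)]),
                        negative=frozenset(picked[len(present_pos):]),
                    )
                )
        else:
            spec = MatchedGenesetSpec(pool_size=int(level), rng_seed=rng_seed)
            pools = _candidate_pools(sig, expr, spec)
            controls = [
                _draw_matched(sig, pools, rng, f"{sig.name}__m{level}_{i}")
                for i in range(n_draws)
            ]
        table = score_signatures(expr, controls)
        for j, ctrl in enumerate(controls):
            sv = ScoreVector(table[ctrl.name], signature_name=ctrl.name)
            rk = rank_cells(sv, params.direction)
            es_values[j] = enrichment_score(rk, sv, part, params.weight_exponent).es
        q = np.quantile(es_values, [0.05, 0.25, 0.5, 0.75, 0.95])
        rows.append(
            {
                "pool_size": level,
                "n_draws": n_draws,
                "es_mean": es_values.mean(),
                "es_sd": es_values.std(ddof=1),
                "es_q05": q[0],
                "es_q25": q[1],
                "es_median": q[2],
                "es_q75": q[3],
                "es_q95": q[4],
            }
        )
    return pd.DataFrame(rows)
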