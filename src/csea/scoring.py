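"""Per-cell signature scoring.

Each cell's normalized log expression profile is first centered and scaled
across genes (z-scored per cell), then a signature score is the mean of the
z-values over the signature's positive genes minus the negative genes:

    score(cell) = (sum_{g in P} z(cell,g) - sum_{g in N} z(cell,g)) / (|P| + |N|)

where P and N are the positive/negative signature genes present in the
matrix. Because of per-cell centering and scaling, scores are invariant to
any per-cell affine transform of the input and the all-genes signature
scores exactly zero.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import sparse

from .types import ExpressionMatrix, GeneSignature, ScoreVector, ValidationError

log = logging.getLogger(__name__)


def _cell_moments(expr: ExpressionMatrix):
    """Per-cell mean and population SD across genes (sparse-friendly)."""
    X = expr.values
    n = expr.n_genes
    if sparse.issparse(X):
        mu = np.asarray(X.mean(axis=1)).ravel()
        sq = np.asarray(X.multiply(X).mean(axis=1)).ravel()
        var = sq - mu**2
    else:
        mu = X.mean(axis=1)
        var = X.var(axis=1, ddof=0)
    var = np.maximum(var, 0.0)
    return mu, np.sqrt(var)


def zscore_cells(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Center and scale each cell's profile across genes (population SD).

    Raises a :class:`ValidationError` naming the first offending cell if a
    profile is constant. The result is dense by construction.
    """
    if expr.n_genes < 2:
        raise ValidationError("z-scoring needs at least 2 genes per cell")
    mu, sd = _cell_moments(expr)
    if np.any(sd == 0):
        bad = expr.cell_ids[np.flatnonzero(sd == 0)[0]]
        raise ValidationError(f"cell {bad!r} has zero variance across genes")
    Z = (expr.dense() - mu[:, None]) / sd[:, None]
    return ExpressionMatrix(Z, expr.cell_ids, expr.gene_ids)


def _present(sig: GeneSignature, gene_ids: np.ndarray):
    idx = pd.Index(gene_ids)
    pos = sorted(sig.positive & set(idx))
    neg = sorted(sig.negative & set(idx))
    dropped = len(sig) - len(pos) - len(neg)
    if dropped:
        log.warning(
            "signature %s: %d of %d genes absent from the matrix and dropped",
            sig.name, dropped, len(sig),
        )
    if not pos and not neg:
        raise ValidationError(f"no gene of signature {sig.name!r} is present in the matrix")
    return idx.get_indexer(pos), idx.get_indexer(neg)


def score_signature(expr_z: ExpressionMatrix, sig: GeneSignature) -> ScoreVector:
    """Score a signature on an already per-cell z-scored matrix.

    The normalization denominator counts only signature genes present in
    the matrix, so scores stay comparable across datasets with different
    gene coverage; absent genes are dropped with a logged warning.
    """
    ipos, ineg = _present(sig, expr_z.gene_ids)
    Z = expr_z.values
    if sparse.issparse(Z):
        total = np.asarray(Z[:, ipos].sum(axis=1)).ravel()
        total -= np.asarray(Z[:, ineg].sum(axis=1)).ravel()
    else:
        total = Z[:, ipos].sum(axis=1) - Z[:, ineg].sum(axis=1)
    score = total / (len(ipos) + len(ineg))
    return ScoreVector(pd.Series(score, index=expr_z.cell_ids), signature_name=sig.name)


def score_signatures(expr: ExpressionMatrix, signatures) -> pd.DataFrame:
    """Score many signatures on a raw (not yet z-scored) matrix.

    Algebraically identical to ``score_signature(zscore_cells(expr), sig)``
    but never densifies the full matrix: per-cell moments are taken over
    all genes and only signature columns are summed, using

        sum_{g in G} z = (sum_{g in G} x - |G| * mu_cell) / sd_cell.

    Returns a cells x signatures DataFrame.
    """
    mu, sd = _cell_moments(expr)
    if np.any(sd == 0):
        bad = expr.cell_ids[np.flatnonzero(sd == 0)[0]]
        raise ValidationError(f"cell {bad!r} has zero variance across genes")
    X = expr.values
    cols = {}
    for sig in signatures:
        ipos, ineg = _present(sig, expr.gene_ids)
        if sparse.issparse(X):
            spos = np.asarray(X[:, ipos].sum(axis=1)).ravel()
            sneg = np.asarray(X[:, ineg].sum(axis=1)).ravel()
        else:
            spos = X[:, ipos].sum(axis=1)
            sneg = X[:, ineg].sum(axis=1)
        raw = (spos - sneg) - (len(ipos) - len(ineg)) * mu
        cols[sig.name] = raw / sd / (len(ipos) + len(ineg))
    return pd.DataFrame(cols, index=expr.cell_ids)
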