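"""Synthetic validation data.

Two generative schemes define the study conditions under which the
enrichment test is validated.

Scheme A (Gaussian mixture) draws per-cell scalar signature scores
directly: control cells come from N(mean1, sd^2) with mean1 = 5 and
sd = 1; each disease (case) cell comes, independently with probability
``outlier_frac``, from a shifted outlier component N(mean2, sd^2) and
otherwise from the control component. The outlier fraction and the mean
separation |mean2 - mean1| are the two knobs that make detection hard.

Scheme B (count matrix) emulates a single-cell experiment in which a
continuous latent cell state drives gene expression: each cell's latent
state z is drawn from the same mixture as scheme A, counts for each gene
follow a negative binomial whose log-mean is a per-gene baseline plus a
loading times (z - mean1) for the differentially expressed (DE) genes,
the matrix is library-size normalized and log1p-transformed, and
case/control labels are assigned by rank-matching the per-cell DE-gene
score to a scheme-A reference. The DE genes are returned as the test
signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
import pandas as pd

from .core import rank_cells
from .scoring import score_signatures
from .types import (
    CellPartition,
    CseaError,
    ExpressionMatrix,
    GeneSignature,
    ScoreVector,
    ValidationError,
)

CONTROL_LABEL = "control"
CASE_LABEL = "case"


@dataclass
class GaussianMixtureSpec:
    """Parameters of the direct score simulation (scheme A)."""

    n_per_group: int = 1000
    mean1: float = 5.0
    sd: float = 1.0
    mean2: float = 7.0
    outlier_frac: float = 0.1
    rng_seed: int = 0
    fixed_outlier_count: bool = False

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValidationError("n_per_group must be >= 2")
        if self.sd <= 0:
            raise ValidationError("sd must be > 0")
        if not 0 <= self.outlier_frac < 1:
            raise ValidationError("outlier_frac must be in [0, 1)")


@dataclass
class CountSimSpec:
    """Parameters of the count-matrix simulation (scheme B).

    ``baseline_log_mean`` (natural-log scale) defaults to per-gene draws
    from N(0.5, 1); ``de_loading`` is the effect of one latent-state unit
    on the log mean of each DE gene; ``dispersion`` is the negative
    binomial size parameter (larger = closer to Poisson).
    """

    n_per_group: int = 300
    n_genes: int = 500
    frac_de_genes: float = 0.1
    de_loading: float = 0.5
    dispersion: float = 10.0
    baseline_log_mean: "np.ndarray | None" = None
    mixture: GaussianMixtureSpec = field(default_factory=GaussianMixtureSpec)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.frac_de_genes <= 1:
            raise ValidationError("frac_de_genes must be in (0, 1]")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be > 0")
        if self.n_genes < 2:
            raise ValidationError("n_genes must be >= 2")


class GaussianSim(NamedTuple):
    scores: ScoreVector
    partition: CellPartition
    outlier_ids: np.ndarray


class CountSim(NamedTuple):
    expr: ExpressionMatrix
    signature: GeneSignature
    partition: CellPartition
    latent: ScoreVector
    trajectory: ScoreVector


def _as_seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


def _cell_names(prefix: str, n: int) -> np.ndarray:
    width = len(str(n))
    return np.asarray([f"{prefix}{i:0{width}d}" for i in range(1, n + 1)], dtype=str)


def simulate_gaussian(spec: GaussianMixtureSpec) -> GaussianSim:
    """Draw scheme-A scores and labels; seed-reproducible.

    By default each case cell independently comes from the outlier
    component with probability ``outlier_frac`` (Bernoulli mixing); with
    ``fixed_outlier_count`` exactly round(outlier_frac * n_per_group) case
    cells are outliers. The realized outlier cells are returned so power
    can be stratified by realized fraction.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_per_group
    ctrl_ids = _cell_names("ctrl", n)
    case_ids = _cell_names("case", n)
    ctrl = rng.normal(spec.mean1, spec.sd, size=n)
    if spec.fixed_outlier_count:
        k = int(round(spec.outlier_frac * n))
        is_outlier = np.zeros(n, dtype=bool)
        is_outlier[rng.choice(n, size=k, replace=False)] = True
    else:
        is_outlier = rng.random(n) < spec.outlier_frac
    case = np.where(
        is_outlier,
        rng.normal(spec.mean2, spec.sd, size=n),
        rng.normal(spec.mean1, spec.sd, size=n),
    )
    scores = pd.Series(
        np.concatenate([ctrl, case]), index=np.concatenate([ctrl_ids, case_ids])
    )
    labels = pd.Series(
        [CONTROL_LABEL] * n + [CASE_LABEL] * n, index=scores.index
    )
    return GaussianSim(
        scores=ScoreVector(scores, signature_name="latent_state"),
        partition=CellPartition(labels, set_of_interest=CASE_LABEL),
        outlier_ids=case_ids[is_outlier],
    )


def rank_match_labels(trajectory_scores: ScoreVector, reference) -> CellPartition:
    """Transfer labels by rank: the i-th ranked cell of the trajectory
    receives the label of the i-th ranked reference cell.

    ``reference`` is a (ScoreVector, CellPartition) pair with the same
    number of cells. Group sizes are preserved exactly.
    """
    ref_scores, ref_part = reference[0], reference[1]
    if len(trajectory_scores) != len(ref_scores):
        raise ValidationError(
            f"cell counts differ: {len(trajectory_scores)} vs {len(ref_scores)}"
        )
    ranked_new = rank_cells(trajectory_scores, "high")
    ranked_ref = rank_cells(ref_scores, "high")
    ref_labels = ref_part.labels.reindex(ranked_ref).to_numpy()
    labels = pd.Series(ref_labels, index=ranked_new)
    labels = labels.reindex(trajectory_scores.cell_ids)
    return CellPartition(labels, set_of_interest=ref_part.set_of_interest)


def simulate_counts(spec: CountSimSpec) -> CountSim:
    """Generate scheme-B data: counts, DE signature, rank-matched labels.

    The latent state reuses the scheme-A draw: the reference mixture is
    the spec's ``mixture`` with ``n_per_group`` and the seed taken from
    the count spec itself, so one ``rng_seed`` reproduces the whole
    replicate. The returned expression matrix holds library-size
    normalized (to the median library), log1p-transformed counts.
    """
    ref_seed, count_seed = _as_seedseq(spec.rng_seed).spawn(2)
    ref_spec = replace(spec.mixture, n_per_group=spec.n_per_group, rng_seed=ref_seed)
    ref = simulate_gaussian(ref_spec)
    rng = np.random.default_rng(count_seed)
    z = ref.scores.scores.to_numpy()
    n_genes = spec.n_genes
    width = len(str(n_genes))
    gene_ids = np.asarray([f"g{i:0{width}d}" for i in range(1, n_genes + 1)], dtype=str)
    if spec.baseline_log_mean is None:
        baseline = rng.normal(0.5, 1.0, size=n_genes)
    else:
        baseline = np.asarray(spec.baseline_log_mean, dtype=float)
        if baseline.shape != (n_genes,):
            raise ValidationError("baseline_log_mean must have one value per gene")
    n_de = max(1, int(round(spec.frac_de_genes * n_genes)))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    loading = np.zeros(n_genes)
    loading[de_idx] = spec.de_loading

    log_mu = baseline[None, :] + np.outer(z - spec.mixture.mean1, loading)
    mu = np.exp(log_mu)
    r = spec.dispersion
    counts = rng.negative_binomial(r, r / (r + mu))
    zero_cells = counts.sum(axis=1) == 0
    if zero_cells.any():
        # one resampling pass for empty cells, then give up
        idx = np.flatnonzero(zero_cells)
        counts[idx] = rng.negative_binomial(r, r / (r + mu[idx]))
        if (counts.sum(axis=1) == 0).any():
            raise CseaError("simulated cells with zero total counts after resampling")

    libsize = counts.sum(axis=1).astype(float)
    target = np.median(libsize)
    norm = np.log1p(counts / libsize[:, None] * target)

    cell_ids = _cell_names("cell", 2 * spec.n_per_group)
    expr = ExpressionMatrix(norm, cell_ids, gene_ids)
    signature = GeneSignature("de_trajectory", positive=frozenset(gene_ids[de_idx]))
    traj = ScoreVector(
        score_signatures(expr, [signature]).iloc[:, 0], signature_name=signature.name
    )
    latent = ScoreVector(
        pd.Series(z, index=cell_ids), signature_name="latent_state"
    )
    part = rank_match_labels(traj, (ref.scores, ref.partition))
    return CountSim(expr=expr, signature=signature, partition=part, latent=latent, trajectory=traj)
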