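"""Shared domain types.

The package works on four in-memory objects: an :class:`ExpressionMatrix`
(cells x genes, library-normalized log expression), a :class:`GeneSignature`
(named positive/negative gene subsets), a :class:`ScoreVector` (one scalar
signature score per cell) and a :class:`CellPartition` (a two-level
condition labelling of the same cells, with one level designated the cell
set of interest S). Enrichment output is collected in
:class:`EnrichmentResult`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse


class CseaError(Exception):
    """Base class for errors raised by this package."""


class FormatError(CseaError):
    """A file does not conform to its declared format."""


class ValidationError(CseaError):
    """An object violates a domain invariant."""


def _as_str_array(ids, what: str) -> np.ndarray:
    arr = np.asarray(list(ids), dtype=str)
    if arr.ndim != 1:
        raise ValidationError(f"{what} must be one-dimensional")
    if len(np.unique(arr)) != arr.size:
        dup = pd.Index(arr)[pd.Index(arr).duplicated()][0]
        raise ValidationError(f"duplicate {what}: {dup!r}")
    return arr


@dataclass
class ExpressionMatrix:
    """Cells x genes matrix of normalized log expression with name indices.

    ``values`` may be a dense ndarray or a scipy sparse matrix; rows are
    cells, columns are genes. Identifiers must be unique and values finite.
    """

    values: "np.ndarray | sparse.spmatrix"
    cell_ids: np.ndarray
    gene_ids: np.ndarray

    def __post_init__(self) -> None:
        self.cell_ids = _as_str_array(self.cell_ids, "cell_ids")
        self.gene_ids = _as_str_array(self.gene_ids, "gene_ids")
        if sparse.issparse(self.values):
            self.values = sparse.csr_matrix(self.values)
            data = self.values.data
        else:
            self.values = np.asarray(self.values, dtype=float)
            if self.values.ndim != 2:
                raise ValidationError("expression values must be a 2-D matrix")
            data = self.values
        if self.values.shape != (self.cell_ids.size, self.gene_ids.size):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{self.cell_ids.size} cells x {self.gene_ids.size} genes"
            )
        if data.size and not np.all(np.isfinite(data)):
            raise ValidationError("expression values contain NaN or Inf")

    @property
    def n_cells(self) -> int:
        return self.cell_ids.size

    @property
    def n_genes(self) -> int:
        return self.gene_ids.size

    def dense(self) -> np.ndarray:
        if sparse.issparse(self.values):
            return np.asarray(self.values.todense(), dtype=float)
        return self.values

    def gene_positions(self, genes) -> np.ndarray:
        """Column indices of ``genes`` (must all be present)."""
        idx = pd.Index(self.gene_ids)
        pos = idx.get_indexer(list(genes))
        if (pos < 0).any():
            missing = [g for g, p in zip(genes, pos) if p < 0]
            raise ValidationError(f"genes not in matrix: {missing[:5]}")
        return pos

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.dense(), index=self.cell_ids, columns=self.gene_ids)


@dataclass(frozen=True)
class GeneSignature:
    """A named gene set, optionally split into positive and negative subsets.

    The score of a cell increases with expression of positive genes and
    decreases with expression of negative genes.
    """

    name: str
    positive: frozenset = field(default_factory=frozenset)
    negative: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "positive", frozenset(self.positive))
        object.__setattr__(self, "negative", frozenset(self.negative))
        if not self.positive and not self.negative:
            raise ValidationError(f"signature {self.name!r} is empty")
        overlap = self.positive & self.negative
        if overlap:
            raise ValidationError(
                f"signature {self.name!r} has genes in both positive and "
                f"negative subsets: {sorted(overlap)[:5]}"
            )

    @property
    def genes(self) -> frozenset:
        return self.positive | self.negative

    def __len__(self) -> int:
        return len(self.positive) + len(self.negative)


@dataclass
class ScoreVector:
    """Per-cell scalar signature scores r_j."""

    scores: pd.Series
    signature_name: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.scores, pd.Series):
            self.scores = pd.Series(self.scores, dtype=float)
        self.scores = self.scores.astype(float)
        self.scores.index = self.scores.index.astype(str)
        if self.scores.index.has_duplicates:
            raise ValidationError("duplicate cell ids in score vector")
        if not np.all(np.isfinite(self.scores.to_numpy())):
            raise ValidationError("scores contain NaN or Inf")

    @property
    def cell_ids(self) -> np.ndarray:
        return self.scores.index.to_numpy()

    def __len__(self) -> int:
        return self.scores.size


@dataclass
class CellPartition:
    """Two-level condition labelling of cells; one level is the set S.

    N is the total cell count and N_H = |S|; both groups must be non-empty.
    """

    labels: pd.Series
    set_of_interest: str

    def __post_init__(self) -> None:
        if not isinstance(self.labels, pd.Series):
            self.labels = pd.Series(self.labels)
        self.labels = self.labels.astype(str)
        self.labels.index = self.labels.index.astype(str)
        if self.labels.index.has_duplicates:
            raise ValidationError("duplicate cell ids in partition")
        levels = set(self.labels.unique())
        if len(levels) != 2:
            raise ValidationError(
                f"partition must have exactly two label levels, got {sorted(levels)}"
            )
        if self.set_of_interest not in levels:
            raise ValidationError(
                f"set_of_interest {self.set_of_interest!r} not among labels {sorted(levels)}"
            )

    @property
    def n(self) -> int:
        return self.labels.size

    @property
    def n_h(self) -> int:
        return int((self.labels == self.set_of_interest).sum())

    @property
    def cell_ids(self) -> np.ndarray:
        return self.labels.index.to_numpy()

    def in_set(self, cell_ids) -> np.ndarray:
        """Boolean membership of ``cell_ids`` (ordered) in S."""
        sub = self.labels.reindex(np.asarray(cell_ids, dtype=str))
        if sub.isna().any():
            raise ValidationError("cell ids not covered by the partition")
        return (sub == self.set_of_interest).to_numpy()


@dataclass
class CseaParams:
    """Parameters of the enrichment test.

    weight_exponent is the exponent applied to |r_j| in the hit weights
    (0 recovers a one-sided Kolmogorov-Smirnov statistic, 1 weights cells
    by score magnitude); direction selects which tail of the ranking is
    tested; pseudo_count switches the permutation p-value to the add-one
    convention (k+1)/(n+1).
    """

    weight_exponent: float = 1.0
    n_permutations: int = 100
    rng_seed: int = 0
    direction: str = "high"
    pseudo_count: bool = False

    def __post_init__(self) -> None:
        if self.weight_exponent < 0:
            raise ValidationError("weight_exponent must be >= 0")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if self.direction not in ("high", "low"):
            raise ValidationError("direction must be 'high' or 'low'")


@dataclass
class EnrichmentResult:
    """Output of the enrichment test for one signature/partition pair."""

    es: float
    argmax_rank: int
    leading_edge: list
    leading_edge_subset: list
    n_r: float
    p_value: "float | None" = None
    corrected_p: "float | None" = None
    signature_name: str = ""
    set_label: str = ""

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.es <= 1 + 1e-12):
            raise ValidationError(f"enrichment score {self.es} outside [0, 1]")
        self.es = float(min(max(self.es, 0.0), 1.0))
        if len(self.leading_edge) != self.argmax_rank:
            raise ValidationError("leading edge length must equal argmax rank")
        if not set(self.leading_edge_subset) <= set(self.leading_edge):
            raise ValidationError("leading-edge subset must lie in the leading edge")
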