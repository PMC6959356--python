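"""Readers and writers for the formats the tool touches.

Supported inputs: Matrix Market triplet matrices with one-column gene and
cell sidecar files (cellranger-style), dense TSV/CSV matrices, GMT gene
set files, and two-column cell -> label tables. Results are written as a
TSV table plus a JSON sidecar holding full leading-edge membership.

Dialect: tab-separated UTF-8; an optional header row is detected by a
non-numeric first data cell. Identifiers are matched exactly and
case-sensitively.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .types import (
    CellPartition,
    EnrichmentResult,
    ExpressionMatrix,
    FormatError,
    GeneSignature,
    ValidationError,
)

log = logging.getLogger(__name__)


def _read_name_column(path) -> np.ndarray:
    """First whitespace-delimited column of a sidecar name file."""
    names = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            names.append(line.split("\t")[0].split(",")[0])
    if not names:
        raise FormatError(f"empty name file: {path}")
    return np.asarray(names, dtype=str)


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def _sniff_sep(path) -> str:
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
    return "\t" if "\t" in first else ","


def _read_dense(path) -> pd.DataFrame:
    sep = _sniff_sep(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n").split(sep)
        second = fh.readline().rstrip("\n").split(sep)
    has_header = any(not _is_number(tok) for tok in first if tok != "")
    # with a header row, a non-numeric first cell in the next row marks an
    # index column of cell ids
    has_index = bool(second and second[0] != "" and not _is_number(second[0]))
    df = pd.read_csv(
        path,
        sep=sep,
        header=0 if has_header else None,
        index_col=0 if (has_header and has_index) else None,
        float_precision="round_trip",
    )
    return df


def _orient(values, n_named_rows: int, n_named_cols: int, what: str):
    """Return values oriented rows x cols to match the sidecar lengths."""
    r, c = values.shape
    if (r, c) == (n_named_rows, n_named_cols) and r == c:
        raise FormatError(
            f"{what}: square matrix with equally sized sidecars is ambiguous; "
            "provide an oriented dense file with headers instead"
        )
    if (r, c) == (n_named_rows, n_named_cols):
        return values
    if (r, c) == (n_named_cols, n_named_rows):
        return values.T
    raise FormatError(
        f"{what}: matrix shape {values.shape} matches neither "
        f"{n_named_rows}x{n_named_cols} nor its transpose"
    )


def read_expression(path_matrix, path_genes=None, path_cells=None) -> ExpressionMatrix:
    """Read an expression matrix, normalizing orientation to cells x genes.

    Matrix Market input requires both sidecar name files; dense TSV/CSV
    input may instead carry gene names in a header row and cell ids in the
    first column.
    """
    path_matrix = Path(path_matrix)
    is_mtx = path_matrix.suffix == ".mtx"
    if not is_mtx:
        with open(path_matrix, encoding="utf-8") as fh:
            is_mtx = fh.readline().startswith("%%MatrixMarket")
    if is_mtx:
        if path_genes is None or path_cells is None:
            raise FormatError("Matrix Market input requires gene and cell sidecar files")
        try:
            mat = spio.mmread(path_matrix)
        except Exception as exc:  # scipy raises bare ValueError on bad triplets
            raise FormatError(f"cannot parse Matrix Market file {path_matrix}: {exc}") from exc
        genes = _read_name_column(path_genes)
        cells = _read_name_column(path_cells)
        mat = sparse.csr_matrix(mat)
        mat = _orient(mat, cells.size, genes.size, str(path_matrix))
        try:
            return ExpressionMatrix(mat, cells, genes)
        except ValidationError:
            raise
    df = _read_dense(path_matrix)
    values = df.to_numpy(dtype=float)
    if path_genes is not None and path_cells is not None:
        genes = _read_name_column(path_genes)
        cells = _read_name_column(path_cells)
        values = _orient(values, cells.size, genes.size, str(path_matrix))
        return ExpressionMatrix(values, cells, genes)
    if df.columns.inferred_type in ("string", "mixed", "unicode"):
        genes = df.columns.to_numpy(dtype=str)
    else:
        raise FormatError(
            f"{path_matrix}: dense input without sidecars must carry a header "
            "row of gene names"
        )
    cells = df.index.to_numpy(dtype=str)
    return ExpressionMatrix(values, cells, genes)


def write_expression(expr: ExpressionMatrix, path_matrix, path_genes=None, path_cells=None) -> None:
    """Write cells x genes; ``.mtx`` writes a triplet file plus sidecars."""
    path_matrix = Path(path_matrix)
    if path_matrix.suffix == ".mtx":
        if path_genes is None or path_cells is None:
            raise FormatError("Matrix Market output requires sidecar paths")
        spio.mmwrite(path_matrix, sparse.coo_matrix(expr.values), precision=17)
        Path(path_genes).write_text("\n".join(expr.gene_ids) + "\n", encoding="utf-8")
        Path(path_cells).write_text("\n".join(expr.cell_ids) + "\n", encoding="utf-8")
        return
    expr.to_dataframe().to_csv(path_matrix, sep="\t", float_format="%.17g")


def read_gmt(path, merge_updn: bool = True) -> list:
    """Parse a GMT gene set file into :class:`GeneSignature` objects.

    With ``merge_updn`` (default), a pair of lines named ``X_UP`` and
    ``X_DN`` merges into one signed signature ``X`` whose positive subset
    is the UP genes and negative subset the DN genes; unpaired lines become
    positive-only signatures.
    """
    raw: dict = {}
    order: list = []
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{ln}: GMT line needs name, description, >=1 gene")
            name, genes = parts[0], [g for g in parts[2:] if g]
            if not genes:
                raise ValidationError(f"{path}:{ln}: gene set {name!r} is empty")
            if name in raw:
                raise ValidationError(f"{path}: duplicate gene set name {name!r}")
            raw[name] = genes
            order.append(name)

    if not merge_updn:
        return [GeneSignature(n, positive=frozenset(raw[n])) for n in order]

    out, done = [], set()
    for name in order:
        if name in done:
            continue
        base = None
        if name.endswith("_UP"):
            base = name[:-3]
        elif name.endswith("_DN"):
            base = name[:-3]
        if base is not None and (base + "_UP" in raw or base + "_DN" in raw):
            up = frozenset(raw.get(base + "_UP", ()))
            dn = frozenset(raw.get(base + "_DN", ()))
            if up and dn and up & dn:
                raise ValidationError(
                    f"{path}: gene(s) {sorted(up & dn)[:5]} appear in both "
                    f"{base}_UP and {base}_DN"
                )
            out.append(GeneSignature(base, positive=up, negative=dn))
            done.update({base + "_UP", base + "_DN"} & set(raw))
        else:
            out.append(GeneSignature(name, positive=frozenset(raw[name])))
            done.add(name)
    return out


def write_gmt(signatures, path) -> None:
    """Write signatures as GMT; signed signatures emit ``_UP``/``_DN`` pairs."""
    with open(path, "w", encoding="utf-8") as fh:
        for sig in signatures:
            if sig.negative:
                if sig.positive:
                    fh.write("\t".join([sig.name + "_UP", ""] + sorted(sig.positive)) + "\n")
                fh.write("\t".join([sig.name + "_DN", ""] + sorted(sig.negative)) + "\n")
            else:
                fh.write("\t".join([sig.name, ""] + sorted(sig.positive)) + "\n")


def read_labels(path, set_label: str) -> CellPartition:
    """Read a two-column cell_id -> label table into a partition."""
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, header=None, dtype=str, comment=None)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (cell_id, label)")
    # tolerate a header row such as "cell<TAB>label"
    first_label = df.iloc[0, 1]
    body = df
    if first_label is not None and first_label.lower() in ("label", "condition", "group", "status"):
        body = df.iloc[1:]
    cells = body.iloc[:, 0]
    labels = body.iloc[:, 1]
    if cells.duplicated().any():
        raise ValidationError(f"{path}: duplicate cell id {cells[cells.duplicated()].iloc[0]!r}")
    series = pd.Series(labels.to_numpy(), index=cells.to_numpy())
    return CellPartition(series, set_of_interest=set_label)


def write_labels(part: CellPartition, path) -> None:
    part.labels.to_csv(path, sep="\t", header=False)


def write_scores(scores_table: pd.DataFrame, path) -> None:
    """Write a cells x signatures score table."""
    scores_table.to_csv(path, sep="\t", float_format="%.10g", index_label="cell_id")


def write_results(results, path_tsv, path_json=None) -> None:
    """Serialize enrichment results to TSV plus a JSON leading-edge sidecar."""
    rows = []
    for r in results:
        rows.append(
            {
                "signature": r.signature_name,
                "set": r.set_label,
                "es": r.es,
                "p_value": r.p_value,
                "corrected_p": r.corrected_p,
                "leading_edge_size": len(r.leading_edge),
                "leading_edge_subset_size": len(r.leading_edge_subset),
            }
        )
    pd.DataFrame(rows).to_csv(path_tsv, sep="\t", index=False, float_format="%.6g")
    if path_json is not None:
        payload = {
            r.signature_name: {
                "leading_edge": list(map(str, r.leading_edge)),
                "leading_edge_subset": list(map(str, r.leading_edge_subset)),
            }
            for r in results
        }
        Path(path_json).write_text(json.dumps(payload, indent=1), encoding="utf-8")
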