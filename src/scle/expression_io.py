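"""Reading, validation and normalization of staged expression matrices.

The analysis consumes a gene x cell matrix of non-negative expression
values together with a cell -> stage assignment whose ordered stage labels
play the role of pseudotime points.  Two input dialects are supported:

* ``dense_tsv`` — first column gene symbol, header row of cell identifiers;
* ``triplet``   — MatrixMarket coordinate file plus one-column gene and
  cell identifier files (row order = gene order, column order = cell order).

Values are log-transformed with the natural ``ln(1 + x)`` before any
scoring; one log base is used consistently package-wide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix

logger = logging.getLogger(__name__)

#: strictly more than six cells per stage are required for the per-stage
#: standard deviations and correlations to be meaningfully estimated
DEFAULT_MIN_CELLS = 7


def _first_duplicate(items) -> str | None:
    seen = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    return None


@dataclass
class ExpressionMatrix:
    """A gene x cell matrix of expression values.

    Parameters
    ----------
    genes
        Unique gene symbols, one per row (length ``M``).
    cells
        Unique cell identifiers, one per column (length ``N``).
    values
        ``M x N`` array of finite, non-negative reals (raw counts or, when
        ``normalized`` is true, ``ln(1+x)`` units).
    normalized
        Whether :func:`normalize_log1p` has been applied.
    """

    genes: tuple[str, ...]
    cells: tuple[str, ...]
    values: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.genes = tuple(str(g) for g in self.genes)
        self.cells = tuple(str(c) for c in self.cells)
        self.values = np.asarray(self.values, dtype=float)
        dup = _first_duplicate(self.genes)
        if dup is not None:
            raise ValueError(f"duplicate gene symbol: {dup!r}")
        dup = _first_duplicate(self.cells)
        if dup is not None:
            raise ValueError(f"duplicate cell identifier: {dup!r}")
        if self.values.shape != (len(self.genes), len(self.cells)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at gene {self.genes[i]!r}, cell {self.cells[j]!r}"
            )
        if not self.normalized and np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative value {self.values[i, j]} at gene "
                f"{self.genes[i]!r}, cell {self.cells[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}


@dataclass
class StageSeries:
    """A normalized expression matrix with an ordered cell -> stage partition.

    The ordered ``stage_order`` labels define the pseudotime axis
    ``t = 1..T``; every retained cell belongs to exactly one stage and every
    stage holds at least ``min_cells`` cells.
    """

    matrix: ExpressionMatrix
    stage_of_cell: dict[str, str]
    stage_order: tuple[str, ...]
    min_cells: int = DEFAULT_MIN_CELLS
    _stage_columns: dict[str, np.ndarray] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.stage_order = tuple(str(s) for s in self.stage_order)
        if len(set(self.stage_order)) != len(self.stage_order):
            raise ValueError("stage_order contains duplicate labels")
        if len(self.stage_order) < 2:
            raise ValueError("need at least two stages (T >= 2)")
        if not self.matrix.normalized:
            raise ValueError("StageSeries requires a normalized matrix")
        known = set(self.stage_order)
        cols: dict[str, list[int]] = {s: [] for s in self.stage_order}
        for j, cell in enumerate(self.matrix.cells):
            try:
                stage = self.stage_of_cell[cell]
            except KeyError:
                raise ValueError(f"cell {cell!r} has no stage assignment") from None
            if stage not in known:
                raise ValueError(
                    f"stage label {stage!r} (cell {cell!r}) not in stage_order"
                )
            cols[stage].append(j)
        for stage in self.stage_order:
            if len(cols[stage]) < self.min_cells:
                raise ValueError(
                    f"stage {stage!r} has {len(cols[stage])} cells; "
                    f"at least {self.min_cells} required"
                )
        self._stage_columns = {s: np.asarray(c, dtype=int) for s, c in cols.items()}

    @property
    def n_stages(self) -> int:
        return len(self.stage_order)

    def stage_columns(self, stage: str) -> np.ndarray:
        """Column indices (into ``matrix.values``) of the cells of ``stage``."""
        return self._stage_columns[stage]

    def stage_values(self, stage: str) -> np.ndarray:
        """The normalized sub-matrix (genes x stage cells) for ``stage``."""
        return self.matrix.values[:, self.stage_columns(stage)]


def load_expression(
    path: str | Path,
    format: str = "dense_tsv",
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read an expression matrix from disk (``normalized=False``).

    ``dense_tsv`` expects gene symbols in the first column and cell
    identifiers in the header.  ``triplet`` expects a MatrixMarket
    coordinate file with companion one-column ``genes_path`` / ``cells_path``
    identifier files; unlisted positions are zero.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression file not found: {path}")
    if format == "dense_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        numeric = df.apply(pd.to_numeric, errors="coerce")
        bad = numeric.isna() & ~df.isna()
        if bad.any().any():
            i, j = np.argwhere(bad.to_numpy())[0]
            raise ValueError(
                f"non-numeric value {df.iat[i, j]!r} at gene "
                f"{df.index[i]!r}, cell {df.columns[j]!r} in {path}"
            )
        if numeric.isna().any().any():
            i, j = np.argwhere(numeric.isna().to_numpy())[0]
            raise ValueError(
                f"missing value at gene {df.index[i]!r}, cell {df.columns[j]!r}"
            )
        return ExpressionMatrix(
            genes=tuple(df.index), cells=tuple(df.columns), values=numeric.to_numpy()
        )
    if format == "triplet":
        if genes_path is None or cells_path is None:
            raise ValueError("triplet format requires genes_path and cells_path")
        genes = _read_identifier_column(genes_path)
        cells = _read_identifier_column(cells_path)
        mat = mmread(str(path))
        values = np.asarray(mat.todense() if hasattr(mat, "todense") else mat, dtype=float)
        if values.shape != (len(genes), len(cells)):
            raise ValueError(
                f"matrix shape {values.shape} does not match {len(genes)} genes "
                f"x {len(cells)} cells from identifier files"
            )
        return ExpressionMatrix(genes=genes, cells=cells, values=values)
    raise ValueError(f"unknown expression format: {format!r}")


def _read_identifier_column(path: str | Path) -> tuple[str, ...]:
    with open(path) as fh:
        return tuple(line.strip() for line in fh if line.strip())


def normalize_log1p(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Apply the elementwise natural-log transform ``x -> ln(1 + x)``.

    Raises if the matrix is already normalized (double-normalization guard).
    """
    if matrix.normalized:
        raise ValueError("matrix is already normalized")
    return ExpressionMatrix(
        genes=matrix.genes,
        cells=matrix.cells,
        values=np.log1p(matrix.values),
        normalized=True,
    )


def assemble_stage_series(
    matrix: ExpressionMatrix,
    labels: pd.DataFrame | dict[str, str],
    stage_order,
    min_cells: int = DEFAULT_MIN_CELLS,
) -> StageSeries:
    """Join a normalized matrix with its cell -> stage assignment.

    Cells absent from ``labels`` are dropped (stage labels typically cover
    only the trajectory subset of the full matrix); the dropped count is
    logged.  A stage with fewer than ``min_cells`` cells, or a label outside
    ``stage_order``, is a hard error.
    """
    if not matrix.normalized:
        raise ValueError("assemble_stage_series requires a normalized matrix")
    if isinstance(labels, pd.DataFrame):
        if labels.shape[1] < 2:
            raise ValueError("label table needs two columns (cell_id, stage_label)")
        mapping = dict(
            zip(labels.iloc[:, 0].astype(str), labels.iloc[:, 1].astype(str))
        )
    else:
        mapping = {str(k): str(v) for k, v in labels.items()}
    keep = [j for j, c in enumerate(matrix.cells) if c in mapping]
    dropped = matrix.n_cells - len(keep)
    if dropped:
        logger.info("dropping %d of %d cells without a stage label", dropped, matrix.n_cells)
    sub = ExpressionMatrix(
        genes=matrix.genes,
        cells=tuple(matrix.cells[j] for j in keep),
        values=matrix.values[:, keep],
        normalized=True,
    )
    return StageSeries(
        matrix=sub,
        stage_of_cell={c: mapping[c] for c in sub.cells},
        stage_order=tuple(stage_order),
        min_cells=min_cells,
    )


def read_labels_tsv(path: str | Path) -> pd.DataFrame:
    """Read a two-column (cell_id, stage_label) TSV with a header row."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"label table {path} needs two columns, found {df.shape[1]}")
    return df


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(matrix.values, index=list(matrix.genes), columns=list(matrix.cells))
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def write_expression_triplet(
    matrix: ExpressionMatrix,
    matrix_path: str | Path,
    genes_path: str | Path,
    cells_path: str | Path,
) -> None:
    mmwrite(str(matrix_path), coo_matrix(matrix.values))
    Path(genes_path).write_text("".join(f"{g}\n" for g in matrix.genes))
    Path(cells_path).write_text("".join(f"{c}\n" for c in matrix.cells))


def write_labels_tsv(stage_of_cell: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cell_id\tstage_label\n")
        for cell, stage in stage_of_cell.items():
            fh.write(f"{cell}\t{stage}\n")
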