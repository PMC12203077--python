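"""Count-matrix containers, I/O, sparsity filtering and TSS normalization.

The central object is :class:`CountMatrix`: a sparse genes × cells matrix of
non-negative integer transcript counts together with gene IDs, cell IDs and a
per-cell individual assignment.  Cells belonging to one individual are kept
contiguous, with individuals in lexicographic order, so that downstream
permutation machinery is reproducible across runs and platforms.

Normalization is total-sum scaling (TSS): each cell's counts are divided by
that cell's total count, so every retained column of the normalized matrix
sums to one.  The F statistic used downstream is scale-invariant, so no
further rescaling (e.g. counts-per-10k) is applied.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .exceptions import DiscIOError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "DesignSpec",
    "read_counts",
    "read_id_file",
    "attach_individuals",
    "filter_sparsity",
    "normalize_tss",
    "write_counts",
]


def _as_str_array(ids) -> np.ndarray:
    return np.asarray(list(ids), dtype=object)


def _check_unique(ids: np.ndarray, what: str) -> None:
    if len(set(ids)) != len(ids):
        seen, dups = set(), set()
        for x in ids:
            (dups if x in seen else seen).add(x)
        raise ValidationError(f"duplicate {what}: {sorted(map(str, dups))[:5]}")


@dataclass
class CountMatrix:
    """Genes × cells sparse integer count matrix with identifiers.

    Parameters
    ----------
    counts
        ``scipy.sparse.csr_matrix`` of shape (M genes, C cells), non-negative
        integer-valued.
    gene_ids, cell_ids
        Unique string identifiers for rows and columns.
    individual_of_cell
        Length-C array of individual labels, or ``None`` before
        :func:`attach_individuals` has been applied.
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    individual_of_cell: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.counts.eliminate_zeros()
        self.gene_ids = _as_str_array(self.gene_ids)
        self.cell_ids = _as_str_array(self.cell_ids)
        if self.individual_of_cell is not None:
            self.individual_of_cell = _as_str_array(self.individual_of_cell)
        self.validate()

    # -- contract -----------------------------------------------------------
    def validate(self) -> None:
        m, c = self.counts.shape
        if len(self.gene_ids) != m:
            raise ValidationError(
                f"{len(self.gene_ids)} gene IDs for a matrix with {m} rows"
            )
        if len(self.cell_ids) != c:
            raise ValidationError(
                f"{len(self.cell_ids)} cell IDs for a matrix with {c} columns"
            )
        _check_unique(self.gene_ids, "gene IDs")
        _check_unique(self.cell_ids, "cell IDs")
        data = self.counts.data
        if data.size:
            if not np.all(np.isfinite(data)):
                raise ValidationError("counts contain non-finite entries")
            if np.any(data < 0):
                raise ValidationError("counts contain negative entries")
            if not np.all(data == np.round(data)):
                raise ValidationError("counts contain non-integer entries")
        if self.individual_of_cell is not None and len(self.individual_of_cell) != c:
            raise ValidationError("individual_of_cell length does not match cells")

    # -- derived quantities -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def individuals(self) -> np.ndarray:
        """Unique individual labels in canonical (lexicographic) order."""
        if self.individual_of_cell is None:
            raise ValidationError("no individual assignment; run attach_individuals")
        return np.unique(self.individual_of_cell)

    def cells_per_individual(self) -> pd.Series:
        """C_j: number of cells for each individual, canonical order."""
        ind = self.individuals
        counts = pd.Series(self.individual_of_cell).value_counts()
        return counts.reindex(ind).astype(int)

    def individual_slices(self) -> dict[str, slice]:
        """Contiguous column slice per individual (requires canonical order)."""
        labels = self.individual_of_cell
        out: dict[str, slice] = {}
        start = 0
        for j, lab in enumerate(labels):
            if j + 1 == len(labels) or labels[j + 1] != lab:
                out[str(lab)] = slice(start, j + 1)
                start = j + 1
        return out


@dataclass
class NormalizedMatrix:
    """TSS-normalized expression: every retained cell column sums to one.

    The zero pattern of the parent :class:`CountMatrix` is preserved exactly:
    a normalized value is zero iff the underlying count was zero.
    """

    values: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    individual_of_cell: np.ndarray

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values).astype(np.float64)
        self.gene_ids = _as_str_array(self.gene_ids)
        self.cell_ids = _as_str_array(self.cell_ids)
        self.individual_of_cell = _as_str_array(self.individual_of_cell)
        if self.values.data.size and np.any(self.values.data < 0):
            raise ValidationError("normalized values must be non-negative")

    @property
    def individuals(self) -> np.ndarray:
        return np.unique(self.individual_of_cell)

    def individual_slices(self) -> dict[str, slice]:
        return CountMatrix.individual_slices(self)  # type: ignore[arg-type]

    def cells_per_individual(self) -> pd.Series:
        ind = self.individuals
        counts = pd.Series(self.individual_of_cell).value_counts()
        return counts.reindex(ind).astype(int)


@dataclass
class DesignSpec:
    """Individual-level design: variables of interest Y and covariates Z.

    Rows are aligned with ``individual_ids``.  Y may hold binary group
    indicators, ordinal scores (e.g. disease severity 0–3) or continuous
    variables; Z holds adjustment covariates and may be empty.  An intercept
    is always added internally by the inference routines and must not be
    included here.
    """

    Y: np.ndarray
    Z: np.ndarray
    individual_ids: np.ndarray
    y_names: list[str] = field(default_factory=list)
    z_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        if self.Y.shape[0] == 1 and len(self.individual_ids) > 1:
            self.Y = self.Y.T
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.size == 0:
            self.Z = np.empty((self.Y.shape[0], 0))
        self.Z = np.atleast_2d(self.Z)
        if self.Z.shape[0] != self.Y.shape[0] and self.Z.shape[1] == self.Y.shape[0]:
            self.Z = self.Z.T
        self.individual_ids = _as_str_array(self.individual_ids)
        if not self.y_names:
            self.y_names = [f"y{k}" for k in range(self.Y.shape[1])]
        if not self.z_names:
            self.z_names = [f"z{k}" for k in range(self.Z.shape[1])]
        self.validate()

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def p(self) -> int:
        return self.Y.shape[1]

    @property
    def q(self) -> int:
        return self.Z.shape[1]

    def validate(self) -> None:
        n, p = self.Y.shape
        if len(self.individual_ids) != n or self.Z.shape[0] != n:
            raise ValidationError("Y, Z and individual_ids row counts differ")
        _check_unique(self.individual_ids, "individual IDs")
        if not np.all(np.isfinite(self.Y)) or not np.all(np.isfinite(self.Z)):
            raise ValidationError("design matrices contain non-finite values")
        q = self.Z.shape[1]
        if n < p + q + 2:
            raise ValidationError(
                f"need N >= p + q + 2 individuals (N={n}, p={p}, q={q})"
            )
        base = np.column_stack([np.ones(n), self.Z])
        r0 = np.linalg.matrix_rank(base)
        for k in range(p):
            if np.linalg.matrix_rank(np.column_stack([base, self.Y[:, k]])) == r0:
                raise ValidationError(
                    f"variable of interest {self.y_names[k]!r} lies in the span "
                    "of the intercept and covariates (collinear)"
                )

    def subset(self, ids) -> "DesignSpec":
        """Rows restricted to / reordered by ``ids``."""
        ids = _as_str_array(ids)
        pos = {str(v): i for i, v in enumerate(self.individual_ids)}
        missing = [str(v) for v in ids if str(v) not in pos]
        if missing:
            raise ValidationError(f"individuals missing from design: {missing[:5]}")
        idx = np.array([pos[str(v)] for v in ids])
        return DesignSpec(
            self.Y[idx], self.Z[idx], ids, list(self.y_names), list(self.z_names)
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_id_file(path) -> np.ndarray:
    """Read one identifier per line, or the first column of a delimited file.

    A header row is detected when the file has multiple columns; in that case
    the first column is used.
    """
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as e:  # pragma: no cover - filesystem dependent
        raise DiscIOError(f"cannot read ID file {path}: {e}") from e
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise DiscIOError(f"ID file {path} is empty")
    sep = "\t" if "\t" in lines[0] else ("," if "," in lines[0] else None)
    if sep is None:
        return _as_str_array(lines)
    df = pd.read_csv(path, sep=sep)
    return _as_str_array(df.iloc[:, 0].astype(str))


def read_counts(path_matrix, path_genes, path_cells) -> CountMatrix:
    """Read a count matrix with gene and cell identifier files.

    ``path_matrix`` may be Matrix Market coordinate format (``.mtx``) or a
    dense delimited text matrix.  Orientation is fixed as genes-in-rows: if
    the stored shape only matches the ID files transposed, the matrix is
    auto-transposed with a log message.
    """
    path_matrix = Path(path_matrix)
    gene_ids = read_id_file(path_genes)
    cell_ids = read_id_file(path_cells)

    try:
        head = path_matrix.read_text(errors="replace")[:64]
    except OSError as e:  # pragma: no cover
        raise DiscIOError(f"cannot read matrix file {path_matrix}: {e}") from e

    if path_matrix.suffix == ".mtx" or head.startswith("%%MatrixMarket"):
        try:
            mat = sp.csr_matrix(mmread(str(path_matrix)))
        except Exception as e:
            raise DiscIOError(f"cannot parse Matrix Market file {path_matrix}: {e}") from e
    else:
        try:
            dense = pd.read_csv(path_matrix, sep=None, engine="python", header=None).to_numpy()
        except Exception as e:
            raise DiscIOError(f"cannot parse dense matrix file {path_matrix}: {e}") from e
        mat = sp.csr_matrix(np.asarray(dense, dtype=float))

    if mat.nnz == 0:
        raise DiscIOError(f"matrix file {path_matrix} has no entries")

    m, c = len(gene_ids), len(cell_ids)
    if mat.shape == (m, c):
        if m == c:
            logger.warning(
                "square matrix: orientation ambiguous, assuming genes in rows"
            )
    elif mat.shape == (c, m):
        logger.info("matrix stored cells × genes; transposing to genes × cells")
        mat = sp.csr_matrix(mat.T)
    else:
        raise DiscIOError(
            f"matrix shape {mat.shape} matches neither ({m} genes, {c} cells) "
            f"nor its transpose"
        )
    return CountMatrix(mat, gene_ids, cell_ids)


def write_counts(cm: CountMatrix, path_matrix, path_genes, path_cells) -> None:
    """Write a CountMatrix as Matrix Market + one-ID-per-line files."""
    mat = cm.counts.astype(np.int64)
    mmwrite(str(path_matrix), mat, field="integer")
    Path(path_genes).write_text("\n".join(map(str, cm.gene_ids)) + "\n")
    Path(path_cells).write_text("\n".join(map(str, cm.cell_ids)) + "\n")


# ---------------------------------------------------------------------------
# Transformations
# ---------------------------------------------------------------------------

def attach_individuals(cm: CountMatrix, cell_meta: pd.DataFrame) -> CountMatrix:
    """Attach the cell → individual mapping and canonicalize cell order.

    ``cell_meta`` needs ``cell_id`` and ``individual`` columns.  Cells are
    regrouped so each individual's cells are contiguous, individuals sorted
    lexicographically; within an individual the original cell order is kept.
    Metadata rows for cells absent from the matrix are ignored with a warning.
    """
    for col in ("cell_id", "individual"):
        if col not in cell_meta.columns:
            raise ValidationError(f"cell metadata lacks required column {col!r}")
    mapping = dict(
        zip(cell_meta["cell_id"].astype(str), cell_meta["individual"].astype(str))
    )
    missing = [str(c) for c in cm.cell_ids if str(c) not in mapping]
    if missing:
        raise ValidationError(
            f"cells missing from metadata: {missing[:5]}"
            + (f" (+{len(missing) - 5} more)" if len(missing) > 5 else "")
        )
    extra = set(mapping) - set(map(str, cm.cell_ids))
    if extra:
        warnings.warn(
            f"{len(extra)} metadata rows refer to cells not in the matrix; ignored",
            stacklevel=2,
        )
    labels = np.array([mapping[str(c)] for c in cm.cell_ids], dtype=object)
    order = np.lexsort((np.arange(len(labels)), labels))
    return CountMatrix(
        sp.csr_matrix(cm.counts[:, order]),
        cm.gene_ids,
        cm.cell_ids[order],
        labels[order],
    )


def filter_sparsity(cm: CountMatrix, max_sparsity: float = 0.8) -> CountMatrix:
    """Drop genes whose zero fraction strictly exceeds ``max_sparsity``.

    The default 0.8 removes genes expressed in fewer than 20% of cells.  The
    boundary is strict: a gene with exactly 80% zeros survives a 0.8
    threshold.  Idempotent.
    """
    if not 0 < max_sparsity <= 1:
        raise ValidationError("max_sparsity must lie in (0, 1]")
    c = cm.n_cells
    nnz = cm.counts.getnnz(axis=1)
    sparsity = 1.0 - nnz / c
    keep = sparsity <= max_sparsity
    if not keep.any():
        raise ValidationError(
            f"all {cm.n_genes} genes exceed {max_sparsity:.0%} sparsity"
        )
    if keep.all():
        return cm
    return CountMatrix(
        sp.csr_matrix(cm.counts[keep]),
        cm.gene_ids[keep],
        cm.cell_ids,
        cm.individual_of_cell,
    )


def normalize_tss(cm: CountMatrix) -> NormalizedMatrix:
    """Total-sum scaling: divide each cell's counts by its total count.

    Cells with a zero total carry no information and are dropped with a
    warning (an individual losing all its cells this way is an error).
    Zeros are preserved exactly.
    """
    if cm.individual_of_cell is None:
        raise ValidationError("attach individuals before normalizing")
    totals = np.asarray(cm.counts.sum(axis=0)).ravel()
    nonzero = totals > 0
    counts = cm.counts
    cell_ids = cm.cell_ids
    labels = cm.individual_of_cell
    if not nonzero.all():
        n_drop = int((~nonzero).sum())
        warnings.warn(f"dropping {n_drop} cells with zero total count", stacklevel=2)
        logger.warning("dropping %d zero-total cells", n_drop)
        lost = set(np.unique(labels)) - set(np.unique(labels[nonzero]))
        if lost:
            raise ValidationError(
                f"individuals lost all cells to zero totals: {sorted(lost)}"
            )
        counts = sp.csr_matrix(counts[:, nonzero])
        cell_ids = cell_ids[nonzero]
        labels = labels[nonzero]
        totals = totals[nonzero]
    values = counts.astype(np.float64) @ sp.diags(1.0 / totals)
    return NormalizedMatrix(sp.csr_matrix(values), cm.gene_ids, cell_ids, labels)
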