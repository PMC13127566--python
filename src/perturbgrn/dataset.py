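"""Annotated cell-by-gene expression matrices with per-cell intervention labels.

The central container mirrors how Perturb-seq screens are distributed: a
cells x genes count matrix plus, for every cell, the symbol of the gene
knocked down in that cell or a non-targeting sentinel marking observational
(control) cells.  A ``stage`` tag tracks where the matrix sits in the
processing chain (``raw_counts`` -> ``normalized`` -> ``zscored``) so that
downstream operations can refuse input at the wrong stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

NON_TARGETING = "non-targeting"

STAGES = ("raw_counts", "normalized", "zscored")
# allowed stage transitions: strictly forward along the chain
_STAGE_ORDER = {s: i for i, s in enumerate(STAGES)}


class StageError(ValueError):
    """Raised when an operation receives data at the wrong processing stage."""


@dataclass
class ExpressionDataset:
    """Cell-by-gene expression matrix with per-cell intervention labels.

    Parameters
    ----------
    matrix
        Non-negative expression values, shape ``(n_cells, n_genes)``.
    cell_labels
        Per-cell intervention target (gene symbol) or the non-targeting
        sentinel for observational cells.
    gene_names
        Ordered, unique gene symbols for the matrix columns.
    stage
        One of ``raw_counts``, ``normalized``, ``zscored``.
    sentinel
        The label marking observational cells (default ``"non-targeting"``).
    """

    matrix: np.ndarray
    cell_labels: np.ndarray
    gene_names: np.ndarray
    stage: str = "raw_counts"
    sentinel: str = NON_TARGETING

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.cell_labels = np.asarray(self.cell_labels, dtype=object)
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-dimensional (cells x genes)")
        if self.matrix.shape[0] != self.cell_labels.shape[0]:
            raise ValueError(
                f"matrix has {self.matrix.shape[0]} rows but "
                f"{self.cell_labels.shape[0]} cell labels"
            )
        if self.matrix.shape[1] != self.gene_names.shape[0]:
            raise ValueError(
                f"matrix has {self.matrix.shape[1]} columns but "
                f"{self.gene_names.shape[0]} gene names"
            )
        if len(set(self.gene_names)) != len(self.gene_names):
            raise ValueError("gene_names must be unique")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        if not np.issubdtype(self.matrix.dtype, np.number):
            raise ValueError("matrix must be numeric")

    # -- basic structure -------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    @property
    def control_mask(self) -> np.ndarray:
        """Boolean mask of observational (non-targeting) cells."""
        return self.cell_labels == self.sentinel

    @property
    def interventional_mask(self) -> np.ndarray:
        return ~self.control_mask

    def perturbations(self) -> list[str]:
        """Sorted unique intervention targets present in the labels."""
        return sorted(set(self.cell_labels) - {self.sentinel})

    def gene_index(self, gene: str) -> int:
        idx = np.flatnonzero(self.gene_names == gene)
        if idx.size == 0:
            raise KeyError(f"gene {gene!r} not measured in dataset")
        return int(idx[0])

    def cells_perturbing(self, gene: str) -> np.ndarray:
        """Row indices of cells in which ``gene`` is the intervention target."""
        return np.flatnonzero(self.cell_labels == gene)

    def expression(self, gene: str, rows: np.ndarray | None = None) -> np.ndarray:
        col = self.matrix[:, self.gene_index(gene)]
        return col if rows is None else col[rows]

    # -- subsetting ------------------------------------------------------

    def subset_cells(self, rows) -> "ExpressionDataset":
        return replace(
            self, matrix=self.matrix[rows], cell_labels=self.cell_labels[rows]
        )

    def subset_genes(self, cols) -> "ExpressionDataset":
        return replace(
            self, matrix=self.matrix[:, cols], gene_names=self.gene_names[cols]
        )

    def with_stage(self, stage: str, matrix: np.ndarray | None = None) -> "ExpressionDataset":
        """Advance the processing stage; only forward transitions are legal."""
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        if _STAGE_ORDER[stage] != _STAGE_ORDER[self.stage] + 1:
            raise StageError(
                f"illegal stage transition {self.stage!r} -> {stage!r}"
            )
        return replace(
            self, matrix=self.matrix if matrix is None else matrix, stage=stage
        )

    def require_stage(self, *stages: str) -> None:
        if self.stage not in stages:
            raise StageError(
                f"operation requires stage in {stages}, got {self.stage!r}"
            )

    def copy(self) -> "ExpressionDataset":
        return replace(
            self,
            matrix=self.matrix.copy(),
            cell_labels=self.cell_labels.copy(),
            gene_names=self.gene_names.copy(),
        )


@dataclass(frozen=True)
class QCThresholds:
    """Two-level quality-control thresholds for perturbational data.

    Defaults are the genome-scale screening values: a perturbation is kept
    if it induced at least ``min_degs`` differentially expressed genes
    (Anderson-Darling test, Benjamini-Hochberg adjusted at ``deg_alpha``),
    retained at least ``min_cells`` cells, and achieved at least
    ``min_knockdown`` relative knockdown of its own target.  At the cell
    level, perturbed cells whose target expression exceeds the
    ``knockdown_percentile``-th percentile of the control distribution are
    discarded, and perturbations left with fewer than
    ``min_effective_cells`` cells are dropped entirely.
    """

    min_degs: int = 50
    min_cells: int = 25
    min_knockdown: float = 0.30
    knockdown_percentile: float = 10.0
    min_effective_cells: int = 100
    deg_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.min_degs < 0 or self.min_cells < 0 or self.min_effective_cells < 0:
            raise ValueError("count thresholds must be non-negative")
        if not 0.0 <= self.min_knockdown <= 1.0:
            raise ValueError("min_knockdown must be in [0, 1]")
        if not 0.0 < self.knockdown_percentile < 100.0:
            raise ValueError("knockdown_percentile must be in (0, 100)")
        if not 0.0 < self.deg_alpha < 1.0:
            raise ValueError("deg_alpha must be in (0, 1)")


#: QC thresholds scaled to simulator-sized inputs (tens of genes, ~100-cell
#: arms) where the genome-scale DEG and effective-cell minima would reject
#: everything.  The DEG rule is disabled (min_degs=0): the two-sample
#: Anderson-Darling p-value has a resolution floor of 0.001, so on a small
#: panel a Benjamini-Hochberg-adjusted lone DEG can never reach
#: significance and the count is uninformative at this scale.
DESK_SCALE_QC = QCThresholds(min_degs=0, min_effective_cells=25)


def read_h5ad(
    path,
    label_field: str = "gene",
    sentinel: str = NON_TARGETING,
) -> ExpressionDataset:
    """Read an annotated h5ad file into an :class:`ExpressionDataset`.

    ``label_field`` names the per-cell (``obs``) column holding the
    perturbed-gene symbol or the non-targeting sentinel.  The processing
    stage is restored from ``uns['stage']`` when present, else assumed raw.
    """
    import anndata as ad
    import scipy.sparse as sp

    adata = ad.read_h5ad(path)
    if label_field not in adata.obs.columns:
        raise KeyError(f"label field {label_field!r} not found in obs")
    X = adata.X
    if sp.issparse(X):
        X = X.toarray()
    X = np.asarray(X)
    if not np.issubdtype(X.dtype, np.number):
        raise ValueError("expression matrix is non-numeric")
    stage = adata.uns.get("stage", "raw_counts")
    return ExpressionDataset(
        matrix=np.asarray(X, dtype=float),
        cell_labels=adata.obs[label_field].astype(str).to_numpy(),
        gene_names=adata.var_names.to_numpy(),
        stage=str(stage),
        sentinel=sentinel,
    )


def write_h5ad(ds: ExpressionDataset, path, label_field: str = "gene") -> None:
    """Write the dataset as h5ad, preserving labels and the stage tag."""
    import anndata as ad
    import pandas as pd

    adata = ad.AnnData(
        X=ds.matrix.copy(),
        obs=pd.DataFrame(
            {label_field: pd.Categorical(ds.cell_labels.astype(str))},
            index=[f"cell{i}" for i in range(ds.n_cells)],
        ),
        var=pd.DataFrame(index=ds.gene_names.astype(str)),
    )
    adata.uns["stage"] = ds.stage
    adata.write_h5ad(path)


def warn(msg: str) -> None:
    warnings.warn(msg, UserWarning, stacklevel=3)
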