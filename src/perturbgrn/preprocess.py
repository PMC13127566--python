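"""Quality control, normalization, gene subsetting, splitting and subsampling.

Perturbational screens carry two nested units of structure: perturbation
*arms* (all cells sharing an intervention target) and individual cells.
QC therefore runs at two levels.  A perturbation arm is retained only if it
(i) induced a minimum number of differentially expressed genes, (ii) kept a
minimum number of cells, and (iii) achieved a minimum relative knockdown of
its own target.  Individual perturbed cells are then discarded when their
target's expression still exceeds a low percentile of the unperturbed
control distribution — i.e. the knockdown visibly failed in that cell — and
arms left with too few effective cells are dropped.  Control cells are
never removed.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dataset import ExpressionDataset, QCThresholds, warn


# ---------------------------------------------------------------------------
# perturbation-level QC primitives
# ---------------------------------------------------------------------------

def count_degs(ds: ExpressionDataset, target: str, alpha: float = 0.05) -> int:
    """Number of genes differentially expressed under a perturbation.

    Compares every measured gene's expression in cells perturbing ``target``
    against the observational cells with the two-sample Anderson-Darling
    test, adjusts p-values across genes with Benjamini-Hochberg, and counts
    genes with adjusted p below ``alpha``.
    """
    pert_rows = ds.cells_perturbing(target)
    ctrl_rows = np.flatnonzero(ds.control_mask)
    if pert_rows.size == 0:
        raise ValueError(f"target {target!r} has no perturbed cells")
    if pert_rows.size < 2 or ctrl_rows.size < 2:
        raise ValueError("need at least 2 cells in each group")
    pvals = np.ones(ds.n_genes)
    for j in range(ds.n_genes):
        a = ds.matrix[pert_rows, j]
        b = ds.matrix[ctrl_rows, j]
        pooled = np.concatenate([a, b])
        if np.unique(pooled).size < 2:
            continue  # constant gene: no evidence of differential expression
        with warnings.catch_warnings():
            # scipy clamps AD p-values to [0.001, 0.25] and warns; clamped
            # genes are far from the alpha boundary either way
            warnings.simplefilter("ignore")
            try:
                pvals[j] = stats.anderson_ksamp([a, b]).pvalue
            except ValueError:
                pvals[j] = 1.0
    adjusted = multipletests(pvals, method="fdr_bh")[1]
    return int(np.sum(adjusted < alpha))


def knockdown_fraction(ds: ExpressionDataset, target: str) -> float:
    """Relative reduction of the target's mean expression versus control.

    Returns ``1 - mean(perturbed) / mean(control)``; 0 means no knockdown,
    1 complete silencing.  Negative values indicate apparent up-regulation.
    """
    j = ds.gene_index(target)  # raises if not measured
    pert = ds.matrix[ds.cells_perturbing(target), j]
    ctrl = ds.matrix[ds.control_mask, j]
    if pert.size == 0 or ctrl.size == 0:
        raise ValueError("both perturbed and control groups must be non-empty")
    ctrl_mean = float(ctrl.mean())
    if ctrl_mean == 0.0:
        warn(f"control mean of {target!r} is zero; knockdown undefined, returning 0")
        return 0.0
    return 1.0 - float(pert.mean()) / ctrl_mean


def qc_report(ds: ExpressionDataset, qc: QCThresholds | None = None) -> pd.DataFrame:
    """Per-perturbation QC table: cell count, DEG count, knockdown, pass flags."""
    qc = qc or QCThresholds()
    if not ds.control_mask.any():
        raise ValueError("no control (non-targeting) cells present")
    rows = []
    for target in ds.perturbations():
        n_cells = int(ds.cells_perturbing(target).size)
        n_degs = count_degs(ds, target, qc.deg_alpha) if n_cells >= 2 else 0
        measured = target in set(ds.gene_names)
        # unmeasured target: knockdown cannot be assessed, criterion waived
        kd = knockdown_fraction(ds, target) if measured else np.nan
        pass_cells = n_cells >= qc.min_cells
        pass_degs = n_degs >= qc.min_degs
        pass_kd = (not measured) or kd >= qc.min_knockdown
        rows.append(
            dict(
                perturbation=target,
                n_cells=n_cells,
                n_degs=n_degs,
                knockdown_fraction=kd,
                pass_cells=pass_cells,
                pass_degs=pass_degs,
                pass_knockdown=pass_kd,
                passed=pass_cells and pass_degs and pass_kd,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "perturbation", "n_cells", "n_degs", "knockdown_fraction",
            "pass_cells", "pass_degs", "pass_knockdown", "passed",
        ],
    )


def qc_perturbation_level(
    ds: ExpressionDataset, qc: QCThresholds | None = None
) -> ExpressionDataset:
    """Drop whole perturbation arms failing the DEG/cell-count/knockdown rules.

    All three thresholds are inclusive ("at least").  Control cells are
    always retained.
    """
    qc = qc or QCThresholds()
    ds.require_stage("raw_counts", "normalized")
    report = qc_report(ds, qc)
    kept = set(report.loc[report["passed"], "perturbation"])
    keep_mask = ds.control_mask | np.isin(ds.cell_labels, list(kept))
    return ds.subset_cells(np.flatnonzero(keep_mask))


def qc_cell_level(
    ds: ExpressionDataset, qc: QCThresholds | None = None
) -> ExpressionDataset:
    """Drop perturbed cells whose knockdown visibly failed, then thin arms.

    A perturbed cell is discarded iff its target gene is measured and its
    expression of that gene exceeds the ``knockdown_percentile``-th
    percentile (linear interpolation between order statistics) of the gene
    in control cells.  Perturbation arms left with fewer than
    ``min_effective_cells`` cells are then dropped entirely.
    """
    qc = qc or QCThresholds()
    ctrl_rows = np.flatnonzero(ds.control_mask)
    if ctrl_rows.size == 0:
        raise ValueError("no control (non-targeting) cells present")
    keep = np.ones(ds.n_cells, dtype=bool)
    measured = set(ds.gene_names)
    for target in ds.perturbations():
        rows = ds.cells_perturbing(target)
        if target in measured:
            j = ds.gene_index(target)
            threshold = np.percentile(
                ds.matrix[ctrl_rows, j], qc.knockdown_percentile
            )
            keep[rows] = ds.matrix[rows, j] <= threshold
        # else: expression unmeasured, per-cell filtering not applicable
        if int(keep[rows].sum()) < qc.min_effective_cells:
            keep[rows] = False
    return ds.subset_cells(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# normalization & gene subsetting
# ---------------------------------------------------------------------------

def normalize_log1p(
    ds: ExpressionDataset, target_sum: float | None = None
) -> ExpressionDataset:
    """Total-count normalization to the median cell total, then log1p.

    Each cell is rescaled so its total expression equals ``target_sum``
    (default: the median of per-cell totals), after which values are
    transformed elementwise by ``log(1 + x)``.
    """
    ds.require_stage("raw_counts")
    totals = ds.matrix.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("cell(s) with zero total counts cannot be normalized")
    if target_sum is None:
        target_sum = float(np.median(totals))
    scaled = ds.matrix * (target_sum / totals)[:, None]
    return ds.with_stage("normalized", matrix=np.log1p(scaled))


def subset_to_perturbed_genes(ds: ExpressionDataset) -> ExpressionDataset:
    """Restrict the gene panel to the (measured) intervention targets.

    Column order follows the original gene ordering; all cells are kept.
    """
    targets = set(ds.perturbations())
    if not targets:
        raise ValueError("no interventional cells present")
    cols = np.flatnonzero(np.isin(ds.gene_names, list(targets)))
    return ds.subset_genes(cols)


def select_hvg(ds: ExpressionDataset, n_genes: int) -> ExpressionDataset:
    """Prevalence filter then highly-variable-gene selection.

    Genes expressed (value > 0) in fewer than 10% of cells are removed;
    the remaining genes are ranked by normalized dispersion — variance/mean
    of the de-logged values, z-scored within 20 mean-quantile bins — and the
    top ``n_genes`` kept (in their original column order).
    """
    ds.require_stage("normalized")
    prevalence = (ds.matrix > 0).mean(axis=0)
    surviving = np.flatnonzero(prevalence >= 0.10)
    if surviving.size < n_genes:
        raise ValueError(
            f"only {surviving.size} genes survive the 10% prevalence filter; "
            f"{n_genes} requested"
        )
    X = np.expm1(ds.matrix[:, surviving])
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1) if X.shape[0] > 1 else np.zeros(surviving.size)
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), 0.0)
    # mean-binning only makes sense when bins are well populated; sparse
    # bins zero out exactly the dispersions they are meant to rank, so
    # small panels fall back to a global z-score (pure dispersion order)
    n_bins = max(1, min(20, surviving.size // 100))
    if n_bins > 1:
        bins = pd.qcut(pd.Series(mean), q=n_bins, duplicates="drop")
        norm_disp = np.empty_like(dispersion)
        for _, idx in pd.Series(range(surviving.size)).groupby(bins, observed=True):
            d = dispersion[idx.to_numpy()]
            sd = d.std(ddof=0)
            norm_disp[idx.to_numpy()] = (d - d.mean()) / sd if sd > 0 else 0.0
    else:
        norm_disp = dispersion
    order = np.argsort(-norm_disp, kind="stable")[:n_genes]
    keep = np.sort(surviving[order])
    return ds.subset_genes(keep)


# ---------------------------------------------------------------------------
# splitting & subsampling
# ---------------------------------------------------------------------------

def split_train_test(
    ds: ExpressionDataset, train_frac: float, seed: int
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Cell-level split stratified by intervention target.

    Within every label group (including non-targeting), ``train_frac`` of
    the cells (floored) go to the training set and the rest to the test
    set.  Deterministic given ``seed``; a single-cell group goes entirely
    to the training set with a warning.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for label in sorted(set(ds.cell_labels)):
        rows = np.flatnonzero(ds.cell_labels == label)
        rows = rng.permutation(rows)
        n_train = int(np.floor(train_frac * rows.size))
        if rows.size == 1:
            warn(f"label group {label!r} has a single cell; assigned to train")
            n_train = 1
        train_idx.append(rows[:n_train])
        test_idx.append(rows[n_train:])
    train_idx = np.sort(np.concatenate(train_idx)).astype(int)
    test_idx = np.sort(np.concatenate(test_idx)).astype(int)
    return ds.subset_cells(train_idx), ds.subset_cells(test_idx)


def subsample(
    ds: ExpressionDataset, mode: str, fraction: float, seed: int
) -> ExpressionDataset:
    """Subsample interventional arms or all cells.

    ``mode='interventional_fraction'`` retains a random fraction of whole
    perturbation arms plus all control cells (fraction 0 yields a purely
    observational dataset).  ``mode='overall_fraction'`` retains a random
    fraction of cells within every label group including control.  Group
    sizes are floored but never emptied below one unit unless the fraction
    is exactly 0.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    if fraction == 1.0:
        return ds
    rng = np.random.default_rng(seed)
    if mode == "interventional_fraction":
        arms = ds.perturbations()
        n_keep = int(np.floor(fraction * len(arms)))
        if fraction > 0 and arms:
            n_keep = max(1, n_keep)
        kept_arms = set(rng.permutation(np.asarray(arms, dtype=object))[:n_keep])
        mask = ds.control_mask | np.isin(ds.cell_labels, list(kept_arms))
        return ds.subset_cells(np.flatnonzero(mask))
    if mode == "overall_fraction":
        keep_rows = []
        for label in sorted(set(ds.cell_labels)):
            rows = np.flatnonzero(ds.cell_labels == label)
            n_keep = int(np.floor(fraction * rows.size))
            if fraction > 0:
                n_keep = max(1, n_keep)
            keep_rows.append(rng.permutation(rows)[:n_keep])
        rows = np.sort(np.concatenate(keep_rows)).astype(int) if keep_rows else []
        return ds.subset_cells(rows)
    raise ValueError(
        "mode must be 'interventional_fraction' or 'overall_fraction'"
    )
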