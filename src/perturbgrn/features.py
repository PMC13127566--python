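"""Four-dimensional expression-summary features for directed gene pairs.

After per-cell z-scoring of the normalized matrix, each directed pair
(g_i, g_j) is summarized by four numbers: the mean observational expression
of g_i and of g_j, and the mean expression of g_i and of g_j over the
interventional cells in which *either* gene of the pair was perturbed.
When a pair has no interventional cells the last two features are filled
with 0 and NaN respectively; the NaN is a deliberate missing marker that
the gradient-boosted classifier consumes natively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset
from .pseudolabel import PseudoLabelSet

ALL = "all"  #: sentinel for build_pair_table(n_negatives=ALL)

FEATURE_COLUMNS = ["f1", "f2", "f3", "f4"]


def zscore_per_cell(ds: ExpressionDataset, axis: str = "cell") -> ExpressionDataset:
    """Z-score the normalized matrix (population SD; constant rows -> 0).

    ``axis='cell'`` (default) standardizes each row across genes, so a
    gene's value becomes its expression relative to the cell's overall
    level.  ``axis='gene'`` standardizes each column across cells instead.
    """
    ds.require_stage("normalized")
    X = ds.matrix
    ax = 1 if axis == "cell" else 0
    if axis not in ("cell", "gene"):
        raise ValueError("axis must be 'cell' or 'gene'")
    mean = X.mean(axis=ax, keepdims=True)
    sd = X.std(axis=ax, keepdims=True)  # population SD (ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(sd > 0, (X - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return ds.with_stage("zscored", matrix=Z)


def pair_features(ds: ExpressionDataset, g_i: str, g_j: str) -> tuple[float, float, float, float]:
    """(f1, f2, f3, f4) for one directed pair from the z-scored matrix."""
    ds.require_stage("zscored")
    if g_i == g_j:
        raise ValueError("pair must consist of two distinct genes")
    obs = np.flatnonzero(ds.control_mask)
    if obs.size == 0:
        raise ValueError("no observational rows")
    i, j = ds.gene_index(g_i), ds.gene_index(g_j)
    inter = np.flatnonzero(
        (ds.cell_labels == g_i) | (ds.cell_labels == g_j)
    )
    f1 = float(ds.matrix[obs, i].mean())
    f2 = float(ds.matrix[obs, j].mean())
    if inter.size == 0:
        return f1, f2, 0.0, float("nan")
    return (
        f1,
        f2,
        float(ds.matrix[inter, i].mean()),
        float(ds.matrix[inter, j].mean()),
    )


@dataclass
class PairFeatureTable:
    """Features and pseudolabels for every ordered gene pair.

    ``table`` holds one row per ordered pair with columns
    ``regulator, target, f1..f4, label``.  ``training_rows`` indexes the
    rows used to fit the classifier (negatives may be subsampled);
    prediction always covers the full table.
    """

    table: pd.DataFrame
    training_rows: np.ndarray

    @property
    def training_view(self) -> pd.DataFrame:
        return self.table.iloc[self.training_rows]

    @property
    def prediction_view(self) -> pd.DataFrame:
        return self.table

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def build_pair_table(
    ds: ExpressionDataset,
    labels: PseudoLabelSet,
    n_negatives: int | str = ALL,
    seed: int = 0,
) -> PairFeatureTable:
    """Assemble the feature table for all ordered pairs, aligned to labels.

    Feature means over the pair's interventional cells are computed from
    per-arm sums (arms are disjoint), which makes the construction linear
    in genes x genes rather than pairs x cells.
    """
    ds.require_stage("zscored")
    genes = list(ds.gene_names)
    label_genes = {g for pair in labels.entries for g in pair}
    if label_genes != set(genes):
        raise ValueError("gene universes of dataset and labels differ")
    obs = np.flatnonzero(ds.control_mask)
    if obs.size == 0:
        raise ValueError("no observational rows")
    obs_mean = ds.matrix[obs].mean(axis=0)

    # per-arm sums over all columns; arm(g) = cells perturbing gene g
    n = len(genes)
    arm_sum = np.zeros((n, n))
    arm_count = np.zeros(n)
    for gi, g in enumerate(genes):
        rows = ds.cells_perturbing(g)
        arm_count[gi] = rows.size
        if rows.size:
            arm_sum[gi] = ds.matrix[rows].sum(axis=0)

    records = []
    for a in range(n):
        for b in range(n):
            if a == b:
                continue
            cnt = arm_count[a] + arm_count[b]
            if cnt == 0:
                f3, f4 = 0.0, np.nan
            else:
                f3 = (arm_sum[a, a] + arm_sum[b, a]) / cnt
                f4 = (arm_sum[a, b] + arm_sum[b, b]) / cnt
            corr, lab = labels.entries[(genes[a], genes[b])]
            records.append(
                (genes[a], genes[b], obs_mean[a], obs_mean[b], f3, f4, lab)
            )
    table = pd.DataFrame(
        records,
        columns=["regulator", "target", "f1", "f2", "f3", "f4", "label"],
    )

    if n_negatives == ALL:
        training_rows = np.arange(len(table))
    else:
        n_negatives = int(n_negatives)
        if n_negatives < 0:
            raise ValueError("n_negatives must be >= 0 or ALL")
        pos = np.flatnonzero(table["label"].to_numpy() == 1)
        neg = np.flatnonzero(table["label"].to_numpy() == 0)
        rng = np.random.default_rng(seed)
        chosen = rng.permutation(neg)[: min(n_negatives, neg.size)]
        training_rows = np.sort(np.concatenate([pos, chosen])).astype(int)
    return PairFeatureTable(table=table, training_rows=training_rows)
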