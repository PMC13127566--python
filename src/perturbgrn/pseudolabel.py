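"""Correlation-derived pseudoannotations for directed gene pairs.

The method's provisional "gold standard" labels each directed gene pair as
putatively regulatory (1) or not (0) by thresholding the absolute
correlation between the two genes' expression, computed on a *balanced*
mixture of interventional and observational cells: all cells in which
either gene was perturbed, plus an equally sized random sample of
observational cells.  Pairs with no interventional cells fall back to the
full observational data.  The balancing keeps strong knockdown arms from
dominating the correlation while still letting interventional covariation
inform the label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataset import ExpressionDataset


@dataclass(frozen=True)
class PseudoLabelConfig:
    """Settings for pseudoannotation.

    ``correlation_threshold`` is the strict bound T: label = 1 iff
    |correlation| > T.  ``correlation_kind`` chooses Pearson (default) or
    Spearman.  ``seed`` drives the per-pair observational subsampling.
    """

    correlation_threshold: float = 0.1
    correlation_kind: str = "pearson"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.correlation_threshold < 0:
            raise ValueError("correlation_threshold must be >= 0")
        if self.correlation_kind not in ("pearson", "spearman"):
            raise ValueError("correlation_kind must be 'pearson' or 'spearman'")


@dataclass
class PseudoLabelSet:
    """Pseudoannotations for every ordered gene pair.

    ``entries`` maps ``(g_i, g_j)`` (i != j) to ``(correlation, label)``;
    correlations and labels are symmetric in pair order by construction.
    """

    entries: dict[tuple[str, str], tuple[float, int]]
    n_genes: int
    threshold: float = 0.1

    def correlation(self, g_i: str, g_j: str) -> float:
        return self.entries[(g_i, g_j)][0]

    def label(self, g_i: str, g_j: str) -> int:
        return self.entries[(g_i, g_j)][1]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                (gi, gj, corr, lab)
                for (gi, gj), (corr, lab) in self.entries.items()
            ],
            columns=["regulator", "target", "correlation", "label"],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def label_from_correlation(correlation: float, threshold: float) -> int:
    """The pseudoannotation rule: 1 iff |correlation| strictly exceeds T."""
    return int(abs(correlation) > threshold)


def intervention_rows(
    ds: ExpressionDataset, genes
) -> tuple[np.ndarray, np.ndarray]:
    """Row indices of cells perturbing any gene in ``genes`` and of controls."""
    genes = set(genes)
    inter = np.flatnonzero(np.isin(ds.cell_labels, list(genes)))
    obs = np.flatnonzero(ds.control_mask)
    return inter, obs


def _pair_rng(seed: int, i: int, j: int) -> np.random.Generator:
    # seeded by the unordered pair so both directions draw the same sample
    lo, hi = (i, j) if i < j else (j, i)
    return np.random.default_rng(np.random.SeedSequence((seed, lo, hi)))


def _correlate(x: np.ndarray, y: np.ndarray, kind: str) -> float:
    if x.size < 3:
        raise ValueError("fewer than 3 usable rows for correlation")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0  # zero-variance guard: correlation undefined, treated as 0
    if kind == "spearman":
        r = stats.spearmanr(x, y).statistic
    else:
        r = np.corrcoef(x, y)[0, 1]
    return float(0.0 if np.isnan(r) else r)


def pair_correlation(
    ds: ExpressionDataset,
    g_i: str,
    g_j: str,
    config: PseudoLabelConfig | None = None,
) -> float:
    """Balanced interventional/observational correlation for one gene pair."""
    config = config or PseudoLabelConfig()
    ds.require_stage("normalized")
    if g_i == g_j:
        raise ValueError("pair must consist of two distinct genes")
    i, j = ds.gene_index(g_i), ds.gene_index(g_j)
    inter, obs = intervention_rows(ds, {g_i, g_j})
    if inter.size == 0:
        rows = obs
    else:
        rng = _pair_rng(config.seed, i, j)
        replace = obs.size < inter.size
        sampled = rng.choice(obs, size=inter.size, replace=replace)
        rows = np.concatenate([inter, sampled])
    # canonical column order makes the result bit-identical in pair order
    a, b = (i, j) if i < j else (j, i)
    return _correlate(ds.matrix[rows, a], ds.matrix[rows, b], config.correlation_kind)


def assign_pseudolabels(
    ds: ExpressionDataset, config: PseudoLabelConfig | None = None
) -> PseudoLabelSet:
    """Pseudoannotate every ordered gene pair by thresholded |correlation|.

    The threshold is strict: |r| exactly equal to T yields label 0.
    Each unordered pair is computed once and mirrored to both directions.
    """
    config = config or PseudoLabelConfig()
    ds.require_stage("normalized")
    genes = list(ds.gene_names)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes")
    T = config.correlation_threshold
    entries: dict[tuple[str, str], tuple[float, int]] = {}
    for a in range(len(genes)):
        for b in range(a + 1, len(genes)):
            r = pair_correlation(ds, genes[a], genes[b], config)
            lab = label_from_correlation(r, T)
            entries[(genes[a], genes[b])] = (r, lab)
            entries[(genes[b], genes[a])] = (r, lab)
    return PseudoLabelSet(entries=entries, n_genes=len(genes), threshold=T)
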