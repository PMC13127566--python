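"""Statistical evaluation of inferred networks against held-out perturbations.

An inferred edge A -> B is judged by comparing the target B's expression in
observational cells against cells where the putative regulator A was
perturbed, both drawn from held-out test data.  The effect size is the
empirical 1-Wasserstein distance between the two samples; its significance
is a two-tailed Mann-Whitney U test.  Edges with p < alpha count as true
positives, others as false positives; statistical precision is TP/(TP+FP)
over the evaluable edges and the mean Wasserstein distance averages the
effect sizes.  The false omission rate (FOR) counterbalances precision:
among a fixed number of randomly sampled pairs *not* inferred, it is the
fraction showing a significant perturbation effect — edges the method
missed.  A good method maximizes the Wasserstein distance while keeping
the FOR low.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import ExpressionDataset
from .inference import EdgeList


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def wasserstein_1d(a, b) -> float:
    """Empirical 1-Wasserstein distance between two samples of reals."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    return float(stats.wasserstein_distance(a, b))


_EXACT_MAX = 8  # exact MWU enumeration up to this per-group size


def mwu_two_tailed(a, b) -> float:
    """Two-tailed Mann-Whitney U p-value.

    For small samples (both sizes <= 8) the p-value is computed by exact
    enumeration of all group assignments of the pooled values (midranks,
    so ties are handled exactly); larger samples use the tie-corrected
    normal approximation with continuity correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    n1, n2 = a.size, b.size
    if n1 <= _EXACT_MAX and n2 <= _EXACT_MAX:
        return _mwu_exact(a, b)
    return float(
        stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
    )


def _u_from_ranks(ranks: np.ndarray, idx, n1: int, n2: int) -> float:
    return float(ranks[list(idx)].sum() - n1 * (n1 + 1) / 2)


def _mwu_exact(a: np.ndarray, b: np.ndarray) -> float:
    """Exact two-sided MWU p by enumeration over pooled-midrank assignments.

    Under the null every assignment of the pooled values to the two groups
    is equally likely; the U statistic is symmetric about n1*n2/2 (U1 and
    U2 are exchangeable), so the two-sided p-value is the probability of a
    deviation from n1*n2/2 at least as large as observed.
    """
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks: exact tie handling
    mu = n1 * n2 / 2.0
    u_obs = _u_from_ranks(ranks, range(n1), n1, n2)
    dev = abs(u_obs - mu)
    total = comb(n1 + n2, n1)
    hits = sum(
        1
        for idx in combinations(range(n1 + n2), n1)
        if abs(_u_from_ranks(ranks, idx, n1, n2) - mu) >= dev - 1e-12
    )
    return hits / total


def auc_over_fractions(fractions, values) -> float:
    """Trapezoidal area of a metric curve over the intervention-fraction axis."""
    fractions = np.asarray(fractions, dtype=float)
    values = np.asarray(values, dtype=float)
    if fractions.size < 2:
        raise ValueError("need at least 2 points")
    if fractions.size != values.size:
        raise ValueError("fractions and values must have equal length")
    if np.any(np.diff(fractions) <= 0):
        raise ValueError("fractions must be strictly increasing")
    return float(np.trapezoid(values, fractions))


# ---------------------------------------------------------------------------
# edge-level evaluation
# ---------------------------------------------------------------------------

@dataclass
class StatEvalReport:
    """Bundle of statistical metrics for an inferred edge list."""

    precision: float
    mean_wasserstein: float
    n_evaluable: int
    n_skipped: int
    alpha: float
    per_edge: pd.DataFrame
    false_omission_rate: float | None = None

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "mean_wasserstein": self.mean_wasserstein,
            "false_omission_rate": self.false_omission_rate,
            "n_evaluable": self.n_evaluable,
            "n_skipped": self.n_skipped,
            "alpha": self.alpha,
        }


def _edge_test(
    ds: ExpressionDataset, regulator: str, target: str
) -> tuple[float, float] | None:
    """(Wasserstein, p) for one edge on ``ds``, or None if not evaluable."""
    rows = ds.cells_perturbing(regulator)
    if rows.size == 0:
        return None
    j = ds.gene_index(target)
    obs = ds.matrix[ds.control_mask, j]
    pert = ds.matrix[rows, j]
    if obs.size == 0:
        return None
    return wasserstein_1d(obs, pert), mwu_two_tailed(obs, pert)


def evaluate_edges(
    edges: EdgeList, test_ds: ExpressionDataset, alpha: float = 0.05
) -> StatEvalReport:
    """Statistical precision and mean Wasserstein distance of an edge list.

    Edges whose regulator has no interventional cells in the test data are
    skipped (reported, excluded from the precision denominator).
    """
    if not test_ds.control_mask.any():
        raise ValueError("test data contains no observational cells")
    records = []
    for regulator, target, score in edges.edges:
        if target not in set(test_ds.gene_names):
            records.append((regulator, target, score, np.nan, np.nan, "skipped"))
            continue
        res = _edge_test(test_ds, regulator, target)
        if res is None:
            records.append((regulator, target, score, np.nan, np.nan, "skipped"))
            continue
        w, p = res
        records.append(
            (regulator, target, score, w, p, "TP" if p < alpha else "FP")
        )
    per_edge = pd.DataFrame(
        records, columns=["regulator", "target", "score", "wasserstein", "p", "status"]
    )
    evaluable = per_edge[per_edge["status"] != "skipped"]
    if len(evaluable) == 0:
        raise ValueError("no evaluable edges: no regulator is perturbed in test data")
    tp = int((evaluable["status"] == "TP").sum())
    return StatEvalReport(
        precision=tp / len(evaluable),
        mean_wasserstein=float(evaluable["wasserstein"].mean()),
        n_evaluable=len(evaluable),
        n_skipped=int((per_edge["status"] == "skipped").sum()),
        alpha=alpha,
        per_edge=per_edge,
    )


def false_omission_rate(
    edges: EdgeList,
    test_ds: ExpressionDataset,
    n_random: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of randomly sampled non-inferred pairs with significant effects.

    Samples ``n_random`` ordered gene pairs (no self-loops) uniformly
    without replacement, removes those present in ``edges``, tests each
    remaining evaluable pair as in :func:`evaluate_edges`, and returns the
    number of significant pairs (false negatives) divided by ``n_random``
    — the denominator stays fixed regardless of removals.  Pairs whose
    regulator has no interventional data count as non-FN.
    """
    genes = list(test_ds.gene_names)
    n = len(genes)
    n_pairs = n * (n - 1)
    if n < 2:
        raise ValueError("gene universe must contain at least 2 genes")
    if n_random > n_pairs:
        raise ValueError(f"n_random={n_random} exceeds available pairs ({n_pairs})")
    rng = np.random.default_rng(seed)
    flat = rng.choice(n_pairs, size=n_random, replace=False)
    inferred = set(edges.pairs())
    fn = 0
    for f in flat:
        a, r = divmod(int(f), n - 1)
        b = r if r < a else r + 1  # skip the diagonal
        pair = (genes[a], genes[b])
        if pair in inferred:
            continue
        res = _edge_test(test_ds, pair[0], pair[1])
        if res is not None and res[1] < alpha:
            fn += 1
    return fn / n_random


# ---------------------------------------------------------------------------
# intervention-fraction sweep
# ---------------------------------------------------------------------------

def intervention_sweep(
    ds: ExpressionDataset,
    fractions,
    seeds,
    k: int,
    method,
    alpha: float = 0.05,
    train_frac: float = 0.8,
    n_random: int = 2000,
) -> pd.DataFrame:
    """Evaluate an inference method across interventional-data fractions.

    For every (fraction, seed): split the (normalized) dataset 80/20
    stratified by intervention target, retain the given fraction of whole
    perturbation arms in the *training* half, run
    ``method(train_ds, k, seed)`` to obtain an edge list, and evaluate it
    on the untouched test half.  Returns a tidy table with one row per
    (fraction, seed) carrying precision, mean Wasserstein and FOR.
    """
    from .preprocess import split_train_test, subsample

    ds.require_stage("normalized")
    rows = []
    for seed in seeds:
        for fraction in fractions:
            train, test = split_train_test(ds, train_frac, seed)
            train = subsample(train, "interventional_fraction", fraction, seed)
            edges = method(train, k, seed)
            report = evaluate_edges(edges, test, alpha)
            for_ = false_omission_rate(
                edges, test, n_random=min(n_random, len(ds.gene_names) * (len(ds.gene_names) - 1)),
                alpha=alpha, seed=seed,
            )
            rows.append(
                dict(
                    fraction=fraction,
                    seed=seed,
                    precision=report.precision,
                    mean_wasserstein=report.mean_wasserstein,
                    false_omission_rate=for_,
                    n_evaluable=report.n_evaluable,
                )
            )
    return pd.DataFrame(rows)


def summarize_sweep(sweep: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of each metric per fraction, plus per-seed AUC-Wasserstein."""
    summary = (
        sweep.groupby("fraction")[["precision", "mean_wasserstein", "false_omission_rate"]]
        .agg(["mean", "std"])
    )
    summary.columns = ["_".join(c) for c in summary.columns]
    return summary.reset_index()


def sweep_auc_wasserstein(sweep: pd.DataFrame) -> pd.Series:
    """AUC of the mean-Wasserstein curve over fractions, per seed."""
    out = {}
    for seed, grp in sweep.groupby("seed"):
        grp = grp.sort_values("fraction")
        out[seed] = auc_over_fractions(
            grp["fraction"].to_numpy(), grp["mean_wasserstein"].to_numpy()
        )
    return pd.Series(out, name="auc_wasserstein")
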