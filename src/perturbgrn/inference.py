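"""Self-training edge scoring and the two reference baselines.

The core inference step fits a small gradient-boosted decision-tree
classifier (LightGBM) to the pair-feature table, using the
correlation-derived pseudoannotations as targets, then scores every
ordered gene pair with the fitted model — a single train-predict loop on
the same data.  The model is expected to "correct" noisy pseudolabels
using the expression-level features, in particular the interventional
means which encode how a pair responds to knockdown.  The top-K pairs by
predicted probability form the inferred network.

Two baselines are provided: ranking pairs directly by absolute balanced
correlation (the score underlying the pseudolabels), and the
mean-difference heuristic which scores (X, Y) by the absolute shift of Y's
mean expression under X's perturbation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset
from .features import FEATURE_COLUMNS, PairFeatureTable
from .pseudolabel import PseudoLabelConfig, assign_pseudolabels


@dataclass(frozen=True)
class BoosterConfig:
    """Gradient-boosting hyperparameters for the pair classifier.

    The defaults deliberately describe a very shallow, heavily regularized
    model: with only four features per pair, tiny trees suffice and large
    ones would memorize the (noisy) pseudolabels instead of correcting
    them.
    """

    num_leaves: int = 5
    max_depth: int = 2
    min_data_in_leaf: int = 5
    learning_rate: float = 0.05
    min_gain_to_split: float = 0.01
    num_iterations: int = 1000
    seed: int = 0
    num_threads: int = 1  # single-threaded by default for reproducibility

    def __post_init__(self) -> None:
        for name in (
            "num_leaves", "max_depth", "min_data_in_leaf",
            "learning_rate", "min_gain_to_split", "num_iterations",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def lgbm_params(self) -> dict:
        return {
            "objective": "binary",
            "num_leaves": self.num_leaves,
            "max_depth": self.max_depth,
            "min_data_in_leaf": self.min_data_in_leaf,
            "learning_rate": self.learning_rate,
            "min_gain_to_split": self.min_gain_to_split,
            "seed": self.seed,
            "num_threads": self.num_threads,
            "deterministic": True,
            "force_row_wise": True,
            "verbosity": -1,
        }


@dataclass
class EdgeList:
    """Ranked directed gene pairs with scores (the inference output)."""

    edges: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        pairs = [(r, t) for r, t, _ in self.edges]
        if any(r == t for r, t in pairs):
            raise ValueError("edge list contains a self-loop")
        if len(set(pairs)) != len(pairs):
            raise ValueError("edge list contains duplicate pairs")
        scores = [s for _, _, s in self.edges]
        if any(a < b for a, b in zip(scores, scores[1:])):
            raise ValueError("edge scores must be non-increasing")

    @property
    def k(self) -> int:
        return len(self.edges)

    def pairs(self) -> list[tuple[str, str]]:
        return [(r, t) for r, t, _ in self.edges]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["regulator", "target", "score"])

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "EdgeList":
        df = pd.read_csv(path, sep="\t")
        return cls(
            edges=[
                (str(r), str(t), float(s))
                for r, t, s in df[["regulator", "target", "score"]].itertuples(
                    index=False
                )
            ]
        )


def self_train_scores(
    table: PairFeatureTable, config: BoosterConfig | None = None
) -> dict[tuple[str, str], float]:
    """Fit the pair classifier on pseudolabels and score every pair.

    Trains on the table's training view (features f1-f4, pseudolabels as
    binary targets; NaN in f4 is consumed natively as missingness) and
    predicts probabilities for every pair in the prediction view.
    Deterministic given the config seed with single-threaded training.
    """
    import lightgbm as lgb

    config = config or BoosterConfig()
    train = table.training_view
    y = train["label"].to_numpy()
    if np.unique(y).size < 2:
        raise ValueError("degenerate pseudolabels: training view has a single class")
    X = train[FEATURE_COLUMNS].to_numpy(dtype=float)
    booster = lgb.train(
        config.lgbm_params(),
        lgb.Dataset(X, label=y.astype(int), params={"verbosity": -1}),
        num_boost_round=config.num_iterations,
    )
    pred = table.prediction_view
    probs = booster.predict(pred[FEATURE_COLUMNS].to_numpy(dtype=float))
    return {
        (r, t): float(p)
        for r, t, p in zip(pred["regulator"], pred["target"], probs)
    }


def top_k_edges(scores: dict[tuple[str, str], float], k: int) -> EdgeList:
    """The k highest-scoring pairs; ties broken lexicographically."""
    if k > len(scores):
        raise ValueError(f"k={k} exceeds the number of scored pairs ({len(scores)})")
    ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return EdgeList(edges=[(r, t, s) for (r, t), s in ranked[:k]])


def baseline_correlation_topk(
    ds: ExpressionDataset, k: int, config: PseudoLabelConfig | None = None
) -> EdgeList:
    """Rank all ordered pairs by absolute balanced correlation, take top k."""
    scores = correlation_scores(ds, config)
    return top_k_edges(scores, k)


def correlation_scores(
    ds: ExpressionDataset, config: PseudoLabelConfig | None = None
) -> dict[tuple[str, str], float]:
    """|balanced correlation| for every ordered pair (the ablation score)."""
    labels = assign_pseudolabels(ds, config)
    return {pair: abs(corr) for pair, (corr, _) in labels.entries.items()}


def baseline_mean_difference_topk(ds: ExpressionDataset, k: int) -> EdgeList:
    """Mean-difference baseline over pairs whose regulator was perturbed.

    Scores (X, Y) by |mean_obs(Y) - mean_{X-perturbed}(Y)|; pairs whose X
    has no interventional cells are excluded from the ranking.
    """
    perturbed = ds.perturbations()
    if not perturbed:
        raise ValueError("no interventional cells present")
    obs_mean = ds.matrix[ds.control_mask].mean(axis=0)
    scores: dict[tuple[str, str], float] = {}
    for x in perturbed:
        rows = ds.cells_perturbing(x)
        arm_mean = ds.matrix[rows].mean(axis=0)
        for j, y in enumerate(ds.gene_names):
            if y == x:
                continue
            scores[(x, y)] = float(abs(obs_mean[j] - arm_mean[j]))
    if k > len(scores):
        raise ValueError(f"k={k} exceeds the number of rankable pairs ({len(scores)})")
    return top_k_edges(scores, k)
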