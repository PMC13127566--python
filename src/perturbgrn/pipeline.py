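"""End-to-end composition: preprocess -> pseudolabel -> features -> train -> evaluate.

``run_pipeline`` chains the library stages with a single configuration
object and returns the inferred edge list together with its statistical
(and optionally biological) evaluation on held-out test cells.  Every
threshold and seed is recorded in the result's ``log`` for provenance.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .bio_eval import BioEvalReport, ReferenceNetwork, precision_recall_f1, restrict_to_genes
from .dataset import NON_TARGETING, ExpressionDataset, QCThresholds
from .features import ALL, build_pair_table
from .inference import BoosterConfig, EdgeList, self_train_scores, top_k_edges
from .preprocess import (
    normalize_log1p,
    qc_cell_level,
    qc_perturbation_level,
    select_hvg,
    split_train_test,
    subsample,
    subset_to_perturbed_genes,
)
from .pseudolabel import PseudoLabelConfig, assign_pseudolabels
from .stat_eval import (
    StatEvalReport,
    auc_over_fractions,
    evaluate_edges,
    false_omission_rate,
    intervention_sweep,
    summarize_sweep,
    sweep_auc_wasserstein,
)


@dataclass
class PipelineConfig:
    """All knobs of the end-to-end run, with screening defaults."""

    k: int = 1000
    qc: QCThresholds = field(default_factory=QCThresholds)
    pseudo: PseudoLabelConfig = field(default_factory=PseudoLabelConfig)
    booster: BoosterConfig = field(default_factory=BoosterConfig)
    n_negatives: int | str = ALL
    alpha: float = 0.05
    seed: int = 0
    train_frac: float = 0.8
    intervention_fraction: float = 1.0
    n_hvg: int | None = None  # observational-only runs may select HVGs
    n_random_for: int = 2000
    label_field: str = "gene"
    sentinel: str = NON_TARGETING

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("k must be positive")

    def log_dict(self) -> dict:
        d = asdict(self)
        d["qc"] = asdict(self.qc)
        d["pseudo"] = asdict(self.pseudo)
        d["booster"] = asdict(self.booster)
        return d


@dataclass
class PipelineResult:
    edges: EdgeList
    stat: StatEvalReport
    bio: BioEvalReport | None
    train: ExpressionDataset
    test: ExpressionDataset
    scores: dict
    log: dict


def preprocess_dataset(
    ds: ExpressionDataset, config: PipelineConfig
) -> ExpressionDataset:
    """QC + normalization + gene subsetting (observational-only data skips QC)."""
    if ds.stage != "raw_counts":
        return ds
    has_intervention = bool(ds.interventional_mask.any())
    if has_intervention:
        ds = qc_perturbation_level(ds, config.qc)
        ds = qc_cell_level(ds, config.qc)
    ds = normalize_log1p(ds)
    if has_intervention and ds.interventional_mask.any():
        ds = subset_to_perturbed_genes(ds)
    elif config.n_hvg is not None:
        ds = select_hvg(ds, config.n_hvg)
    return ds


def infer_edges(
    train: ExpressionDataset,
    k: int,
    seed: int | None = None,
    pseudo: PseudoLabelConfig | None = None,
    booster: BoosterConfig | None = None,
    n_negatives: int | str = ALL,
    return_scores: bool = False,
):
    """Pseudolabel -> features -> one train-predict loop -> top-K edges."""
    from .features import zscore_per_cell

    pseudo = pseudo or PseudoLabelConfig()
    booster = booster or BoosterConfig()
    if seed is not None:
        pseudo = PseudoLabelConfig(
            correlation_threshold=pseudo.correlation_threshold,
            correlation_kind=pseudo.correlation_kind,
            seed=seed,
        )
        booster = BoosterConfig(
            **{**asdict(booster), "seed": seed}
        )
    labels = assign_pseudolabels(train, pseudo)
    zs = zscore_per_cell(train)
    table = build_pair_table(zs, labels, n_negatives=n_negatives, seed=booster.seed)
    scores = self_train_scores(table, booster)
    edges = top_k_edges(scores, k)
    return (edges, scores) if return_scores else edges


def run_pipeline(
    ds: ExpressionDataset,
    config: PipelineConfig | None = None,
    reference: ReferenceNetwork | None = None,
) -> PipelineResult:
    """Execute the full inference and evaluation chain on one dataset."""
    config = config or PipelineConfig()
    processed = _stage("preprocess", preprocess_dataset, ds, config)

    n_pairs = processed.n_genes * (processed.n_genes - 1)
    if config.k > n_pairs:
        raise ValueError(
            f"[validate] k={config.k} exceeds the {n_pairs} ordered gene pairs"
        )

    train, test = _stage(
        "split", split_train_test, processed, config.train_frac, config.seed
    )
    if config.intervention_fraction < 1.0:
        train = _stage(
            "subsample", subsample, train, "interventional_fraction",
            config.intervention_fraction, config.seed,
        )

    edges, scores = _stage(
        "infer", infer_edges, train, config.k, None, config.pseudo,
        config.booster, config.n_negatives, True,
    )
    stat = _stage("eval-stat", evaluate_edges, edges, test, config.alpha)
    stat.false_omission_rate = _stage(
        "eval-stat", false_omission_rate, edges, test,
        min(config.n_random_for, n_pairs), config.alpha, config.seed,
    )
    bio = None
    if reference is not None:
        ref = restrict_to_genes(reference, set(processed.gene_names))
        bio = _stage("eval-bio", precision_recall_f1, edges, ref)
    return PipelineResult(
        edges=edges, stat=stat, bio=bio, train=train, test=test,
        scores=scores, log=config.log_dict(),
    )


def run_sweep(
    ds: ExpressionDataset,
    config: PipelineConfig,
    fractions,
    seeds,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Intervention-fraction sweep of the full method.

    Returns the per-(fraction, seed) metric table, its per-fraction
    mean +/- SD summary, and the per-seed AUC of the mean-Wasserstein
    curve.
    """
    if len(list(fractions)) == 0:
        raise ValueError("[sweep] empty fraction list")
    processed = _stage("preprocess", preprocess_dataset, ds, config)

    def method(train_ds, k, seed):
        return infer_edges(
            train_ds, k, seed, config.pseudo, config.booster, config.n_negatives
        )

    sweep = intervention_sweep(
        processed, fractions, seeds, config.k, method,
        alpha=config.alpha, train_frac=config.train_frac,
        n_random=config.n_random_for,
    )
    return sweep, summarize_sweep(sweep), sweep_auc_wasserstein(sweep)


def _stage(name: str, fn, *args):
    """Run one pipeline stage, tagging errors with the stage name."""
    try:
        return fn(*args)
    except Exception as exc:
        if str(exc).startswith("["):
            raise
        raise type(exc)(f"[{name}] {exc}") from exc
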