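"""Biological evaluation against reference interaction networks.

Inferred edges are compared to curated interaction databases (protein
complexes, protein-protein interaction networks, ChIP-seq derived
regulons) consumed as plain two-column edge lists.  Several references can
be pooled into one network, restricted to the measured genes, and
optionally narrowed to the subset of reference pairs that show a
significant perturbation effect in the data at hand ("significant
subset").  Precision, recall and F1 then score the overlap between
inferred and reference pairs.

Most interaction databases are undirected (a complex membership carries no
regulator/target orientation), so the default matching is canonical
unordered matching: an inferred directed pair hits an undirected reference
pair regardless of orientation, and two opposite directed hits to the same
reference pair count once toward recall.  Strict directed matching is
available for TF->target style references.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import ExpressionDataset, warn
from .inference import EdgeList
from .stat_eval import _edge_test


@dataclass
class ReferenceNetwork:
    """A set of reference gene pairs, directed or canonically undirected."""

    pairs: frozenset
    directed: bool = False
    source: str = ""

    def __post_init__(self) -> None:
        canon = set()
        for a, b in self.pairs:
            if a == b:
                continue
            canon.add((a, b) if self.directed else tuple(sorted((a, b))))
        object.__setattr__(self, "pairs", frozenset(canon))

    def __len__(self) -> int:
        return len(self.pairs)

    def genes(self) -> set:
        return {g for pair in self.pairs for g in pair}


def read_edge_list(path, directed: bool = False, source: str = "") -> ReferenceNetwork:
    """Parse a two-column TSV of gene symbols into a reference network.

    Rows are deduplicated (canonically for undirected networks) and
    self-loop rows dropped with a warning.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return ReferenceNetwork(pairs=frozenset(), directed=directed, source=source)
    if len(df) and df.shape[1] < 2:
        raise ValueError("edge list must have at least two columns")
    pairs = set()
    n_loops = 0
    for row in df.itertuples(index=False):
        a, b = str(row[0]), str(row[1])
        if a == b:
            n_loops += 1
            continue
        pairs.add((a, b))
    if n_loops:
        warn(f"dropped {n_loops} self-loop row(s) from {path}")
    return ReferenceNetwork(pairs=frozenset(pairs), directed=directed, source=source)


def pool_networks(nets: list[ReferenceNetwork]) -> ReferenceNetwork:
    """Union of several reference networks under a common convention.

    If any input network is undirected, the pooled network is undirected
    (directed pairs lose their orientation on canonicalization).
    """
    if not nets:
        raise ValueError("need at least one network to pool")
    directed = all(n.directed for n in nets)
    pairs = set()
    for n in nets:
        pairs |= n.pairs
    return ReferenceNetwork(
        pairs=frozenset(pairs),
        directed=directed,
        source="+".join(filter(None, (n.source for n in nets))),
    )


def restrict_to_genes(net: ReferenceNetwork, genes) -> ReferenceNetwork:
    """Keep only pairs whose both endpoints are in ``genes``."""
    genes = set(genes)
    return ReferenceNetwork(
        pairs=frozenset(
            p for p in net.pairs if p[0] in genes and p[1] in genes
        ),
        directed=net.directed,
        source=net.source,
    )


def significant_subset(
    net: ReferenceNetwork, ds: ExpressionDataset, alpha: float = 0.05
) -> ReferenceNetwork:
    """Reference pairs showing a significant perturbation effect in ``ds``.

    Each reference pair is treated like an inferred edge and tested with
    the Mann-Whitney procedure of the statistical evaluation; pairs with
    p < alpha are kept.  For undirected pairs, both orientations are
    tested and the pair is kept if either is significant.  Non-evaluable
    pairs (no interventional cells for the putative regulator) are
    dropped.
    """
    if not ds.interventional_mask.any():
        raise ValueError("dataset contains no interventional cells")
    measured = set(ds.gene_names)
    kept = set()
    for a, b in net.pairs:
        directions = [(a, b)] if net.directed else [(a, b), (b, a)]
        for reg, tgt in directions:
            if tgt not in measured:
                continue
            res = _edge_test(ds, reg, tgt)
            if res is not None and res[1] < alpha:
                kept.add((a, b))
                break
    return ReferenceNetwork(pairs=frozenset(kept), directed=net.directed, source=net.source)


@dataclass
class BioEvalReport:
    """Precision/recall/F1 of an inferred edge list against a reference."""

    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
        }


def precision_recall_f1(edges: EdgeList, net: ReferenceNetwork) -> BioEvalReport:
    """Set-overlap metrics between inferred pairs and a reference network.

    Precision judges every inferred edge individually (TP = inferred edges
    present in the reference); recall counts each reference pair at most
    once, however many inferred orientations hit it.  F1 is the harmonic
    mean, 0 when precision + recall = 0.  Scores are ignored (set
    semantics).
    """
    if edges.k == 0:
        raise ValueError("empty inference")
    if len(net) == 0:
        raise ValueError("empty reference network")
    inferred = edges.pairs()

    def canon(p):
        return p if net.directed else tuple(sorted(p))

    tp = sum(1 for p in inferred if canon(p) in net.pairs)
    fp = len(inferred) - tp
    hit_refs = {canon(p) for p in inferred if canon(p) in net.pairs}
    fn = len(net) - len(hit_refs)
    precision = tp / (tp + fp)
    recall = len(hit_refs) / len(net)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return BioEvalReport(
        precision=precision, recall=recall, f1=f1, tp=tp, fp=fp, fn=fn
    )
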