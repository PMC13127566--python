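"""Statistical and biological evaluation of an inferred edge list.

Infers a network from a simulated screen, then evaluates it two ways on
held-out test cells: statistically (is the target's expression shifted
when the putative regulator is knocked down? Wasserstein distance +
Mann-Whitney test) and biologically (overlap with a reference network,
here the simulator's ground truth written to a TSV edge list, as one
would consume CORUM/STRING-style references).
"""

import tempfile
from pathlib import Path

from perturbgrn import (
    DESK_SCALE_QC,
    PipelineConfig,
    SimulationConfig,
    precision_recall_f1,
    read_edge_list,
    restrict_to_genes,
    run_pipeline,
    simulate,
)

ds, truth = simulate(
    SimulationConfig(n_genes=30, n_edges=18, n_obs_cells=250,
                     cells_per_perturbation=100, seed=8)
)

with tempfile.TemporaryDirectory() as tmp:
    ref_path = Path(tmp) / "reference.tsv"
    truth.to_tsv(ref_path)
    # reference edge lists are two-column TSVs; direction is often
    # unreliable in curated databases, so the default match is undirected
    reference = read_edge_list(ref_path, directed=False)

result = run_pipeline(ds, PipelineConfig(k=30, qc=DESK_SCALE_QC, n_random_for=400))

stat = result.stat
print("statistical evaluation on held-out cells:")
print(f"  precision (edges with Mann-Whitney p < 0.05): {stat.precision:.2f} "
      f"over {stat.n_evaluable} evaluable edges")
print(f"  mean Wasserstein distance: {stat.mean_wasserstein:.3f} "
      "(expression shift of the target under regulator knockdown)")
print(f"  false omission rate: {stat.false_omission_rate:.3f} "
      "(significant effects among randomly sampled non-inferred pairs)")

reference = restrict_to_genes(reference, set(result.train.gene_names))
bio = precision_recall_f1(result.edges, reference)
print("\nbiological evaluation against the reference network:")
print(f"  precision {bio.precision:.2f}  recall {bio.recall:.2f}  "
      f"F1 {bio.f1:.3f}  (TP={bio.tp}, FP={bio.fp}, FN={bio.fn})")
print("a good method keeps precision high while the Wasserstein distance "
      "stays large and the false omission rate small")
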