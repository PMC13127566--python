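"""Two-level quality control on a perturbational screen.

Constructs a screen in which each knockdown arm violates (or satisfies) a
known QC rule, prints the per-perturbation QC report, and shows which arms
survive.  The three perturbation-level rules are: enough differentially
expressed genes (Anderson-Darling + Benjamini-Hochberg), enough cells, and
enough knockdown of the arm's own target.
"""

import numpy as np

from perturbgrn import QCThresholds, qc_cell_level, qc_perturbation_level, qc_report
from perturbgrn.dataset import NON_TARGETING, ExpressionDataset

rng = np.random.default_rng(7)
n_genes, n_ctrl = 12, 60
genes = [f"G{j+1}" for j in range(n_genes)]

# arms: target -> (cells, strongly shifted genes, knockdown ratio)
arms = {
    "G1": (30, 6, 0.5),    # healthy arm
    "G2": (20, 6, 0.5),    # too few cells
    "G3": (30, 2, 0.5),    # too few DEGs
    "G4": (30, 6, 0.9),    # only 10% knockdown
}
ctrl = rng.normal(10, 1, size=(n_ctrl, n_genes))
blocks, labels = [ctrl], [NON_TARGETING] * n_ctrl
for target, (n_cells, n_degs, ratio) in arms.items():
    j = genes.index(target)
    block = rng.normal(10, 1, size=(n_cells, n_genes))
    hit = [c for c in range(n_genes) if genes[c] not in arms][: n_degs - 1]
    block[:, hit] += 8.0
    block[:, j] = ctrl[:, j].mean() * ratio
    blocks.append(block)
    labels += [target] * n_cells

ds = ExpressionDataset(
    matrix=np.vstack(blocks),
    cell_labels=np.asarray(labels, dtype=object),
    gene_names=np.asarray(genes, dtype=object),
)

qc = QCThresholds(min_degs=5, min_cells=25, min_knockdown=0.25,
                  min_effective_cells=5)
print("per-perturbation QC report:")
print(qc_report(ds, qc).to_string(index=False))

kept = qc_perturbation_level(ds, qc)
print(f"\nsurviving perturbations: {kept.perturbations()}")
print("(G2 lost to the cell floor, G3 to the DEG floor, G4 to the "
      "knockdown floor)")

effective = qc_cell_level(kept, qc)
for target in effective.perturbations():
    n_before = int((kept.cell_labels == target).sum())
    n_after = int((effective.cell_labels == target).sum())
    print(f"cell-level filter on {target}: {n_before} -> {n_after} cells "
          "(cells above the control 10th percentile of the target removed)")
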