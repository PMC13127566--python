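import numpy as np
import pytest

from perturbgrn import (
    DESK_SCALE_QC,
    NON_TARGETING,
    ExpressionDataset,
    PipelineConfig,
    SimulationConfig,
    simulate,
)


def make_dataset(matrix, labels, genes=None, stage="raw_counts"):
    matrix = np.asarray(matrix, dtype=float)
    if genes is None:
        genes = [f"G{j+1}" for j in range(matrix.shape[1])]
    return ExpressionDataset(
        matrix=matrix,
        cell_labels=np.asarray(labels, dtype=object),
        gene_names=np.asarray(genes, dtype=object),
        stage=stage,
    )


def make_toy_screen(rng, arms, n_genes=12, n_ctrl=60, n_deg_shift=8.0):
    """Construct a screen where each arm's QC fate is known by design.

    ``arms`` maps target -> (n_cells, n_strong_degs, knockdown_ratio).
    Control expression ~ N(10, 1); DEG genes are shifted by ``n_deg_shift``
    SD in the arm; the arm's own target column is held exactly constant at
    8.0 in control and scaled by the (binary-exact) knockdown ratio in the
    arm, so the measured knockdown fraction is exact.
    """
    genes = [f"G{j+1}" for j in range(n_genes)]
    ctrl = rng.normal(10, 1, size=(n_ctrl, n_genes))
    for target in arms:
        ctrl[:, genes.index(target)] = 8.0
    blocks, labels = [ctrl], [NON_TARGETING] * n_ctrl
    for target, (n_cells, n_degs, kd_ratio) in arms.items():
        j = genes.index(target)
        block = rng.normal(10, 1, size=(n_cells, n_genes))
        # other arms' target columns must match control exactly, else they
        # would register as spurious DEGs of this arm
        for other in arms:
            block[:, genes.index(other)] = 8.0
        shifted = [c for c in range(n_genes) if genes[c] not in arms][: n_degs - 1]
        block[:, shifted] += n_deg_shift
        block[:, j] = 8.0 * kd_ratio  # the target itself is DEG number n_degs
        blocks.append(block)
        labels += [target] * n_cells
    return make_dataset(np.vstack(blocks), labels, genes=genes)


@pytest.fixture(scope="session")
def small_sim():
    """A small fast screen: 20 genes, 10 edges, full intervention."""
    config = SimulationConfig(
        n_genes=20, n_edges=10, n_obs_cells=120, cells_per_perturbation=60, seed=5
    )
    return simulate(config)


@pytest.fixture(scope="session")
def default_sim():
    """The full desk-scale screen at the generator's default conditions."""
    return simulate(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def default_pipeline_result(default_sim):
    """One end-to-end run on the default screen, shared across tests."""
    from perturbgrn import run_pipeline

    ds, _ = default_sim
    config = PipelineConfig(k=30, qc=DESK_SCALE_QC, n_random_for=1000)
    return run_pipeline(ds, config)


@pytest.fixture
def obs_only_ds():
    """Purely observational dataset, normalized stage."""
    from perturbgrn import normalize_log1p

    rng = np.random.default_rng(42)
    X = rng.poisson(5.0, size=(80, 6)).astype(float) + 1.0
    ds = make_dataset(X, [NON_TARGETING] * 80)
    return normalize_log1p(ds)
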