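"""Wasserstein distances, Mann-Whitney testing, precision/FOR, sweeps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from perturbgrn import (
    NON_TARGETING,
    EdgeList,
    auc_over_fractions,
    evaluate_edges,
    false_omission_rate,
    intervention_sweep,
    mwu_two_tailed,
    wasserstein_1d,
)
from conftest import make_dataset

finite_floats = st.floats(-50, 50, allow_nan=False)


class TestWasserstein:
    def test_identical_samples(self):
        a = [1.0, 2.0, 5.0]
        assert wasserstein_1d(a, a) == 0.0

    def test_point_masses(self):
        assert wasserstein_1d([0.0], [1.0]) == 1.0

    @given(
        st.lists(finite_floats, min_size=1, max_size=10),
        st.floats(-5, 5, allow_nan=False),
    )
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_translation_property(self, a, c):
        b = [x + c for x in a]
        assert wasserstein_1d(a, b) == pytest.approx(abs(c), abs=1e-9)

    @given(
        st.lists(finite_floats, min_size=1, max_size=6),
        st.lists(finite_floats, min_size=1, max_size=6),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_symmetry_and_nonnegativity(self, a, b):
        assert wasserstein_1d(a, b) == pytest.approx(wasserstein_1d(b, a))
        assert wasserstein_1d(a, b) >= 0

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            wasserstein_1d([], [1.0])


class TestMannWhitney:
    def test_complete_separation_small_sample(self):
        # all 20 assignments enumerated; the observed extreme split has
        # point probability 1/20 per tail -> two-sided p = 0.1
        assert mwu_two_tailed([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_equal_multisets(self):
        assert mwu_two_tailed([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            n1, n2 = rng.integers(2, 7, size=2)
            a = rng.normal(size=n1)
            b = rng.normal(size=n2)
            ours = mwu_two_tailed(a, b)
            ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert ours == pytest.approx(ref.pvalue, abs=1e-12)

    def test_null_rejection_rate_large_samples(self):
        rng = np.random.default_rng(2)
        rejections = 0
        n_sims = 400
        for _ in range(n_sims):
            a = rng.normal(size=100)
            b = rng.normal(size=100)
            rejections += mwu_two_tailed(a, b) < 0.05
        assert rejections / n_sims == pytest.approx(0.05, abs=0.025)

    def test_empty_sample_errors(self):
        with pytest.raises(ValueError):
            mwu_two_tailed([], [1.0])


class TestAucOverFractions:
    def test_trapezoid_arithmetic(self):
        assert auc_over_fractions([0, 1], [0.2, 0.4]) == pytest.approx(0.3)

    def test_constant_curve(self):
        assert auc_over_fractions([0, 0.5, 1], [0.7, 0.7, 0.7]) == pytest.approx(0.7)

    def test_single_point_errors(self):
        with pytest.raises(ValueError):
            auc_over_fractions([0.5], [0.1])

    def test_unsorted_fractions_error(self):
        with pytest.raises(ValueError):
            auc_over_fractions([0.5, 0.25, 1.0], [1, 2, 3])


def _eval_screen(seed=0, strong_edges=2, null_edges=2, n_obs=60, n_arm=40):
    """Screen with known strong and null regulator->target effects.

    Genes come in (regulator, target) pairs; strong pairs shift the target
    by 5 units in the regulator's arm, null pairs do not.
    """
    rng = np.random.default_rng(seed)
    n_pairs = strong_edges + null_edges
    n_genes = 2 * n_pairs
    genes = [f"G{j+1}" for j in range(n_genes)]
    blocks = [rng.normal(10, 1, size=(n_obs, n_genes))]
    labels = [NON_TARGETING] * n_obs
    edges = []
    for p in range(n_pairs):
        reg, tgt = 2 * p, 2 * p + 1
        block = rng.normal(10, 1, size=(n_arm, n_genes))
        block[:, reg] = 0.0
        if p < strong_edges:
            block[:, tgt] += 5.0
        blocks.append(block)
        labels += [genes[reg]] * n_arm
        edges.append((genes[reg], genes[tgt], 1.0 - 0.01 * p))
    ds = make_dataset(np.vstack(blocks), labels, genes=genes)
    return ds, EdgeList(edges=edges)


class TestEvaluateEdges:
    def test_strong_shifts_all_true_positive(self):
        ds, edges = _eval_screen(strong_edges=4, null_edges=0)
        report = evaluate_edges(edges, ds, alpha=0.05)
        assert report.precision == 1.0
        assert report.n_evaluable == 4
        assert report.mean_wasserstein == pytest.approx(5.0, abs=0.5)

    def test_mixture_precision_near_half(self):
        ds, edges = _eval_screen(strong_edges=10, null_edges=10, seed=3)
        report = evaluate_edges(edges, ds, alpha=0.05)
        assert report.precision == pytest.approx(0.5, abs=0.1)

    def test_unperturbed_regulator_skipped(self):
        ds, edges = _eval_screen(strong_edges=2, null_edges=0)
        extra = EdgeList(
            edges=list(edges.edges) + [("G2", "G1", 0.0)]  # G2 never perturbed
        )
        report = evaluate_edges(extra, ds, alpha=0.05)
        assert report.n_skipped == 1
        assert report.n_evaluable == 2

    def test_no_evaluable_edges_errors(self):
        ds, _ = _eval_screen(strong_edges=1, null_edges=0)
        orphan = EdgeList(edges=[("G2", "G1", 1.0)])
        with pytest.raises(ValueError, match="no evaluable"):
            evaluate_edges(orphan, ds)


class TestFalseOmissionRate:
    def test_all_sampled_pairs_inferred_gives_zero(self):
        ds, _ = _eval_screen(strong_edges=1, null_edges=0)  # 2 genes, 2 pairs
        both = EdgeList(edges=[("G1", "G2", 1.0), ("G2", "G1", 0.9)])
        assert false_omission_rate(both, ds, n_random=2, seed=0) == 0.0

    def test_strong_missed_edges_are_found(self):
        ds, edges = _eval_screen(strong_edges=4, null_edges=0)
        empty_inference = EdgeList(edges=[("G2", "G1", 1.0)])
        n_pairs = 8 * 7
        rate = false_omission_rate(empty_inference, ds, n_random=n_pairs, seed=1)
        # exactly the 4 strong regulator->target pairs are significant, plus
        # compensatory shifts induced in the arms; rate must at least catch
        # the 4 designed edges
        assert rate >= 4 / n_pairs

    def test_bounds_and_denominator(self):
        ds, edges = _eval_screen(strong_edges=2, null_edges=2)
        rate = false_omission_rate(edges, ds, n_random=20, seed=2)
        assert 0.0 <= rate <= 1.0

    def test_oversampling_errors(self):
        ds, _ = _eval_screen(strong_edges=1, null_edges=0)
        with pytest.raises(ValueError, match="exceeds"):
            false_omission_rate(EdgeList(edges=[("G1", "G2", 1.0)]), ds, n_random=50)


class TestInterventionSweep:
    def test_bookkeeping_single_cell(self, small_sim):
        from perturbgrn import DESK_SCALE_QC, PipelineConfig
        from perturbgrn.pipeline import preprocess_dataset
        from perturbgrn.preprocess import split_train_test
        from perturbgrn import baseline_mean_difference_topk

        ds, _ = small_sim
        config = PipelineConfig(qc=DESK_SCALE_QC)
        proc = preprocess_dataset(ds, config)

        def method(train, k, seed):
            return baseline_mean_difference_topk(train, k)

        sweep = intervention_sweep(
            proc, [1.0], [0], k=10, method=method, n_random=100
        )
        assert len(sweep) == 1
        # row must equal a manual run of the same split
        train, test = split_train_test(proc, 0.8, 0)
        edges = method(train, 10, 0)
        report = evaluate_edges(edges, test, 0.05)
        assert sweep.loc[0, "precision"] == report.precision
        assert sweep.loc[0, "mean_wasserstein"] == pytest.approx(
            report.mean_wasserstein
        )
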