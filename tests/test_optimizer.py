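"""Replicate SQP engine: objective, initialisation, recovery, aggregation."""

import math

import numpy as np
import pytest

from hdxsolver.forward_model import PeptideSystem
from hdxsolver.hx_io import ValidationError
from hdxsolver.optimizer import (
    OptimizerSettings,
    aggregate,
    flag_collapse,
    initial_guess,
    objective_mse,
    optimize_replicate,
    run_ensemble,
)

from conftest import make_dataset, make_peptide, uniform_kch
from test_io import make_ensemble


class TestObjective:
    def test_generating_rates_give_zero(self):
        ds = make_dataset([(1, 2)], timepoints=(1.0, 10.0), rfu_rows=[
            tuple(1 - math.exp(-0.1 * t) for t in (1.0, 10.0))
        ])
        assert objective_mse(np.array([0.1]), ds) == pytest.approx(0.0, abs=1e-16)

    def test_all_zero_vs_all_one_is_unity(self):
        ds = make_dataset([(1, 2)], timepoints=(1.0, 10.0),
                          rfu_rows=[(1.0, 1.0)])
        assert objective_mse(np.array([1e-18]), ds) == pytest.approx(1.0, abs=1e-12)

    def test_hand_summed_toy_case(self):
        t = (1.0, 2.0)
        ds = make_dataset([(1, 2), (2, 3)], timepoints=t,
                          rfu_rows=[(0.3, 0.5), (0.2, 0.6)])
        k = {2: 0.2, 3: 0.1}
        model = {
            (0, 0): 1 - math.exp(-0.2 * 1), (0, 1): 1 - math.exp(-0.2 * 2),
            (1, 0): 1 - math.exp(-0.1 * 1), (1, 1): 1 - math.exp(-0.1 * 2),
        }
        exp = {(0, 0): 0.3, (0, 1): 0.5, (1, 0): 0.2, (1, 1): 0.6}
        expected = sum((model[c] - exp[c]) ** 2 for c in model) / 4
        got = objective_mse(np.array([0.2, 0.1]), ds)
        assert got == pytest.approx(expected, rel=1e-12)


class TestInitialGuess:
    def test_deterministic_per_replicate(self):
        s = OptimizerSettings(base_seed=42)
        kch = np.full(20, 100.0)
        assert np.array_equal(initial_guess(s, 3, kch), initial_guess(s, 3, kch))
        assert not np.array_equal(initial_guess(s, 3, kch), initial_guess(s, 4, kch))

    def test_respects_bounds(self):
        s = OptimizerSettings(base_seed=1, init_scale=1e6)
        kch = np.full(100, 5.0)
        x = initial_guess(s, 0, kch)
        assert np.all(x > s.lower_bound) and np.all(x < kch)

    def test_mean_matches_scale(self):
        s = OptimizerSettings(base_seed=0, init_scale=1.0)
        kch = np.full(100_000, 1e9)  # effectively unclipped
        x = initial_guess(s, 0, kch)
        assert x.mean() == pytest.approx(1.0, rel=0.02)


def single_residue_dataset(lnp_values, kch_value=100.0):
    """Non-overlapping 2-residue peptides: each competent residue isolated."""
    spans, rfu_rows = [], []
    t = (0.25, 1.0, 5.0, 20.0, 60.0, 240.0, 480.0)
    for i, lnp in enumerate(lnp_values):
        start = 1 + 3 * i
        k = kch_value * math.exp(-lnp)
        spans.append((start, start + 1))
        rfu_rows.append(tuple(1 - math.exp(-k * tt) for tt in t))
    ds = make_dataset(spans, timepoints=t, rfu_rows=rfu_rows)
    return ds


class TestOptimizeReplicate:
    def test_closed_form_recovery_on_isolated_residues(self):
        truth = [0.5, 2.0, 4.0, 6.0, 8.0]
        ds = single_residue_dataset(truth)
        kch = uniform_kch(ds, 100.0)
        ens = run_ensemble(ds, kch, OptimizerSettings(replicates=3, base_seed=9))
        med = np.median(ens.lnp, axis=0)
        rmse = np.sqrt(np.mean((med - np.array(truth)) ** 2))
        assert rmse < 0.01

    def test_boundary_recovery_unprotected(self):
        ds = single_residue_dataset([0.0, 0.0])
        kch = uniform_kch(ds, 100.0)
        ens = run_ensemble(ds, kch, OptimizerSettings(replicates=2, base_seed=3))
        assert np.all(np.abs(ens.lnp) < 0.05)

    def test_descent_from_initial_guess(self, toy_dataset):
        s = OptimizerSettings(replicates=2, base_seed=11)
        system = PeptideSystem(toy_dataset)
        kch = np.full(len(system.residues), 100.0)
        x0 = initial_guess(s, 0, kch)
        kobs, mse, _ = optimize_replicate(toy_dataset, kch, s, 0)
        assert mse <= system.mse(x0)

    def test_bounds_respected(self, toy_dataset):
        s = OptimizerSettings(replicates=2, base_seed=5)
        kch = np.full(len(toy_dataset.competent_residues), 100.0)
        kobs, _, _ = optimize_replicate(toy_dataset, kch, s, 1)
        assert np.all(kobs >= s.lower_bound) and np.all(kobs <= kch)


class TestRunEnsemble:
    def test_bit_reproducible_under_seed(self, toy_dataset):
        kch = uniform_kch(toy_dataset, 100.0)
        s = OptimizerSettings(replicates=3, base_seed=77)
        e1 = run_ensemble(toy_dataset, kch, s)
        e2 = run_ensemble(toy_dataset, kch, s)
        assert np.array_equal(e1.lnp, e2.lnp)
        assert e1.seeds == e2.seeds

    def test_two_replicates_agree_on_exact_data(self):
        ds = single_residue_dataset([1.0, 3.0, 5.0])
        kch = uniform_kch(ds, 100.0)
        ens = run_ensemble(ds, kch, OptimizerSettings(replicates=2, base_seed=2))
        assert np.allclose(ens.lnp[0], ens.lnp[1], atol=0.01)

    def test_single_replicate_rejected(self):
        with pytest.raises(ValidationError, match="2 replicates"):
            OptimizerSettings(replicates=1)

    def test_all_lnp_within_bounds(self, toy_dataset):
        kch = uniform_kch(toy_dataset, 100.0)
        ens = run_ensemble(toy_dataset, kch, OptimizerSettings(replicates=2))
        assert np.all(ens.kobs >= ens.settings.lower_bound)
        assert np.all(ens.kobs <= ens.kch[None, :] + 1e-300)
        assert np.all(ens.lnp >= -1e-9)


class TestAggregate:
    def test_median_robust_to_outlier(self):
        ens = make_ensemble([[3.0, 1], [5.0, 1], [100.0, 1]])
        med, _ = aggregate(ens, "median")
        mean, _ = aggregate(ens, "mean")
        assert med.values[0] == 5.0
        assert mean.values[0] == pytest.approx(36.0)

    def test_identical_replicates_zero_iqr(self):
        ens = make_ensemble([[2.0, 4.0]] * 5)
        for method in ("median", "mean", "kmeans"):
            centre, iqr = aggregate(ens, method)
            assert np.allclose(centre.values, [2.0, 4.0])
            assert np.allclose(iqr, 0.0)

    def test_kmeans_dominant_cluster(self):
        ens = make_ensemble([[1.0, 0], [1.0, 0], [1.0, 0], [9.0, 0], [9.0, 0]])
        centre, _ = aggregate(ens, "kmeans")
        assert centre.values[0] == pytest.approx(1.0)

    def test_unknown_method_rejected(self):
        ens = make_ensemble([[1.0, 2.0], [1.0, 2.0]])
        with pytest.raises(ValueError, match="method"):
            aggregate(ens, "mode")


class TestCollapse:
    @pytest.mark.parametrize(
        "spread,expected", [(25.0, True), (0.0, False), (20.0, True)]
    )
    def test_iqr_threshold_inclusive(self, spread, expected):
        # IQR of [0, 0, s, s] is exactly s under linear interpolation
        vals = np.array([[0.0], [0.0], [spread], [spread]])
        ens = make_ensemble(np.hstack([vals, np.ones((4, 1))]))
        flags = flag_collapse(ens)
        assert flags[1] is expected
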