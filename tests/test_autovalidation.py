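"""Covariance auto-validation statistics against independent Pearson oracles."""

import math

import numpy as np
import pytest

from hdxsolver.autovalidation import (
    classify,
    delta_r_matrix,
    evaluate_against_reference,
    pairwise_r,
    r_hat_reference,
    residue_histograms,
)
from hdxsolver.forward_model import ProtectionVector
from hdxsolver.hx_io import ValidationError

from test_io import make_ensemble


def pearson(a, b):
    """Independent two-pass Pearson correlation (the test oracle)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    am, bm = a - a.mean(), b - b.mean()
    return float((am * bm).sum() / math.sqrt((am * am).sum() * (bm * bm).sum()))


def oracle_r_hat(lnp, include_diagonal=True):
    m = lnp.shape[0]
    vals = []
    for i in range(m):
        for j in range(m):
            if i == j:
                if include_diagonal:
                    vals.append(1.0)
                continue
            vals.append(pearson(lnp[i], lnp[j]))
    return float(np.mean(vals))


class TestPairwiseR:
    def test_identical_replicates_all_ones(self):
        lnp = np.tile(np.array([1.0, 3.0, 2.0, 5.0]), (4, 1))
        vm = pairwise_r(lnp)
        assert np.allclose(vm.matrix, 1.0)
        assert vm.r_hat == pytest.approx(1.0)

    def test_anticorrelated_pair_averages_to_zero(self):
        lnp = np.array([[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        vm = pairwise_r(lnp)
        assert vm.matrix[0, 1] == pytest.approx(-1.0)
        assert vm.r_hat == pytest.approx(0.0, abs=1e-12)

    def test_matches_scalar_oracle_on_random_fixtures(self, rng):
        for _ in range(5):
            lnp = rng.uniform(0, 14, size=(6, 9))
            vm = pairwise_r(lnp)
            for i in range(6):
                for j in range(6):
                    expected = 1.0 if i == j else pearson(lnp[i], lnp[j])
                    assert vm.matrix[i, j] == pytest.approx(expected, abs=1e-12)
            assert vm.r_hat == pytest.approx(oracle_r_hat(lnp), abs=1e-12)

    def test_symmetry_diagonal_and_range(self, rng):
        lnp = rng.normal(5, 2, size=(8, 12))
        vm = pairwise_r(lnp)
        assert np.array_equal(vm.matrix, vm.matrix.T)
        assert np.allclose(np.diag(vm.matrix), 1.0)
        assert np.nanmax(np.abs(vm.matrix)) <= 1.0 + 1e-12
        assert -1.0 <= vm.r_hat <= 1.0

    def test_off_diagonal_mode(self, rng):
        lnp = rng.uniform(0, 10, size=(4, 6))
        vm = pairwise_r(lnp, include_diagonal=False)
        assert vm.r_hat == pytest.approx(oracle_r_hat(lnp, False), abs=1e-12)

    def test_zero_variance_replicate_excluded(self, rng):
        lnp = rng.uniform(0, 10, size=(4, 6))
        lnp[2, :] = 3.0
        vm = pairwise_r(lnp)
        assert np.isnan(vm.matrix[2, 0]) and np.isnan(vm.matrix[2, 2])
        assert vm.n_missing > 0
        assert np.isfinite(vm.r_hat)

    def test_too_few_replicates_or_residues(self):
        with pytest.raises(ValidationError):
            pairwise_r(np.ones((1, 5)))
        with pytest.raises(ValidationError):
            pairwise_r(np.ones((3, 1)))


class TestRHatReference:
    def test_perfect_agreement(self):
        ref = np.array([1.0, 4.0, 2.0, 6.0])
        lnp = np.tile(ref, (5, 1))
        assert r_hat_reference(lnp, ref) == pytest.approx(1.0)

    def test_mixed_correlated_anticorrelated(self):
        ref = np.array([1.0, 2.0, 3.0])
        lnp = np.vstack([ref, ref[::-1]])
        assert r_hat_reference(lnp, ref) == pytest.approx(0.0, abs=1e-12)

    def test_matches_replicate_mean_of_oracle(self, rng):
        ref = rng.uniform(0, 14, 10)
        lnp = rng.uniform(0, 14, size=(6, 10))
        expected = np.mean([pearson(row, ref) for row in lnp])
        assert r_hat_reference(lnp, ref) == pytest.approx(expected, abs=1e-12)

    def test_accepts_protection_vector(self, rng):
        lnp = rng.uniform(0, 10, size=(3, 5))
        ens = make_ensemble(lnp, residues=(4, 5, 6, 7, 8))
        ref = ProtectionVector((4, 5, 6, 7, 8), lnp[0])
        got = r_hat_reference(ens, ref)
        expected = np.mean([pearson(row, lnp[0]) for row in lnp])
        assert got == pytest.approx(expected, abs=1e-12)


class TestDeltaR:
    def test_sequential_omission_equals_brute_force(self, rng):
        """Leave-one-out dR-hat must equal recomputing both means from
        scratch with the independent Pearson oracle, residue by residue."""
        lnp = rng.uniform(0, 14, size=(5, 12))
        got = delta_r_matrix(lnp).delta_r
        full = oracle_r_hat(lnp)
        for j in range(12):
            sub = np.delete(lnp, j, axis=1)
            assert got[j] == pytest.approx(full - oracle_r_hat(sub), abs=1e-12)

    def test_noise_residue_negative_consistent_residues(self, rng):
        base = rng.uniform(0, 10, 9)
        lnp = np.tile(base, (8, 1)) + rng.normal(0, 0.05, size=(8, 9))
        lnp = np.hstack([lnp, rng.uniform(0, 10, size=(8, 1))])  # residue 9: noise
        delta = delta_r_matrix(lnp).delta_r
        assert delta[9] < 0

    def test_consistent_leverage_residue_positive_in_noisy_ensemble(self, rng):
        # 8 residues of independent noise plus one replicate-consistent
        # residue far from the rest: it dominates every pairwise correlation
        lnp = rng.normal(5, 0.8, size=(8, 8))
        lnp = np.hstack([lnp, np.full((8, 1), 20.0)])
        delta = delta_r_matrix(lnp).delta_r
        assert delta[8] > 0

    def test_perfectly_consistent_all_near_zero(self):
        lnp = np.tile(np.array([1.0, 5.0, 3.0, 8.0]), (6, 1))
        delta = delta_r_matrix(lnp).delta_r
        assert all(abs(v) < 1e-12 for v in delta.values())

    def test_needs_three_residues(self):
        with pytest.raises(ValidationError):
            delta_r_matrix(np.ones((3, 2)))


class TestClassify:
    @pytest.mark.parametrize(
        "value,expected",
        [(0.71, "high"), (0.7, "fair"), (0.5, "fair"), (0.49, "low"),
         (1.0, "high"), (-0.2, "low")],
    )
    def test_bins(self, value, expected):
        assert classify(value) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            classify(1.5)


class TestHistograms:
    def test_identical_values_single_bin(self):
        lnp = np.full((100, 1), 3.4)
        counts, edges = residue_histograms(lnp).histograms[0]
        assert counts.sum() == 100
        assert counts.max() == 100

    def test_integer_aligned_edges(self):
        lnp = np.array([[0.5], [1.5]])
        counts, edges = residue_histograms(lnp, bin_width=1.0).histograms[0]
        assert list(counts) == [1, 1]
        assert edges[0] == 0.0 and edges[-1] == 2.0

    def test_counts_sum_to_replicates(self, rng):
        lnp = rng.uniform(0, 10, size=(40, 6))
        hists = residue_histograms(lnp).histograms
        assert all(c.sum() == 40 for c, _ in hists.values())

    def test_uniform_draws_roughly_flat(self, rng):
        lnp = rng.uniform(0, 10, size=(5000, 1))
        counts, edges = residue_histograms(lnp).histograms[0]
        from scipy.stats import chisquare
        assert chisquare(counts).pvalue > 1e-4


class TestEvaluateAgainstReference:
    def test_perfect_separation_auc_one(self, rng):
        # accurate block tracks truth tightly; inaccurate block is noise
        truth = np.linspace(0, 12, 10)
        good = np.tile(truth[:6], (10, 1)) + rng.normal(0, 0.05, (10, 6))
        bad = rng.uniform(0, 12, size=(10, 4))
        ens = make_ensemble(np.hstack([good, bad]))
        ev = evaluate_against_reference(ens, dict(enumerate(truth, start=1)))
        rmse_good = [ev.rmse[r] for r in range(1, 7)]
        rmse_bad = [ev.rmse[r] for r in range(7, 11)]
        assert max(rmse_good) < min(rmse_bad)
        if ev.roc_auc is not None:
            assert ev.roc_auc > 0.7

    def test_one_class_labels_reported_missing(self):
        lnp = np.tile(np.array([1.0, 5.0, 3.0]), (4, 1))
        ens = make_ensemble(lnp)
        ev = evaluate_against_reference(ens, {1: 1.0, 2: 5.0, 3: 3.0})
        # perfectly consistent ensemble: dR-hat ~ 0 everywhere, no sign split
        assert ev.roc_auc is None

    def test_enrichment_ratio_arithmetic(self):
        from hdxsolver.autovalidation import _enrichments
        med_err = np.array([0.5] * 8 + [2.5] * 2 + [0.5] * 5 + [2.5] * 5)
        delta = np.array([1.0] * 10 + [-1.0] * 10)
        enrich, excess = _enrichments(med_err, delta)
        assert enrich == pytest.approx(100 * (0.8 / 0.5 - 1))  # 60%
        assert excess == pytest.approx(100 * (0.5 / 0.2))      # 250%
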