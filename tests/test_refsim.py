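"""Reference-data generator: determinism, coverage, round-trip fidelity."""

import numpy as np
import pytest

from hdxsolver import refsim
from hdxsolver.coverage import compute_occupancy
from hdxsolver.forward_model import kobs_from_lnp, model_rfu_table
from hdxsolver.hx_io import ValidationError
from hdxsolver.intrinsic_rates import compute_kch


class TestSimulateLnp:
    def test_deterministic_under_seed(self):
        a = refsim.simulate_lnp(50, seed=4)
        b = refsim.simulate_lnp(50, seed=4)
        assert np.array_equal(a.values, b.values)

    def test_range_and_positivity(self):
        p = refsim.simulate_lnp(200, lnp_range=(0.0, 14.0), seed=1)
        assert p.values.min() >= 0.0
        assert p.values.max() <= 14.0

    def test_spatial_autocorrelation(self):
        p = refsim.simulate_lnp(10_000, seed=2)
        v = p.values
        lag1 = np.corrcoef(v[:-1], v[1:])[0, 1]
        assert lag1 > 0.5

    def test_two_term_mode(self):
        contacts = np.array([0.0, 2.0, 4.0])
        hbonds = np.array([0.0, 1.0, 0.0])
        p = refsim.simulate_lnp(3, mode="two-term", contacts=contacts,
                                hbonds=hbonds, beta_c=0.35, beta_h=2.0)
        assert np.allclose(p.values, [0.0, 2.7, 1.4])

    def test_two_term_requires_counts(self):
        with pytest.raises(ValidationError, match="counts"):
            refsim.simulate_lnp(5, mode="two-term")


class TestSimulateMap:
    @pytest.mark.parametrize("target", [1.5, 3.0, 5.0])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_coverage_and_redundancy_tolerance(self, target, seed):
        n = 60
        spans = refsim.simulate_map(n, (5, 12), target, seed=seed)
        covered = set()
        for s, e in spans:
            covered.update(range(s, e + 1))
        assert covered == set(range(1, n + 1))
        realised = sum(e - s + 1 for s, e in spans) / n
        assert abs(realised - target) <= 0.2 * target

    def test_infeasible_parameters_rejected(self):
        with pytest.raises(ValidationError):
            refsim.simulate_map(10, (20, 25), 2.0, seed=0)

    def test_dense_layout_full_ladder(self):
        spans = refsim.simulate_map(40, (5, 10), 1.0, seed=3, layout="dense")
        starts = {s for s, _ in spans}
        assert starts == set(range(1, 37))  # a peptide starts at every residue
        assert max(e for _, e in spans) == 40


class TestProjectRfu:
    def make_refset(self, noise=0.0, seed=5):
        rng = np.random.default_rng(seed)
        n = 30
        seq = refsim.random_sequence(n, rng)
        truth = refsim.simulate_lnp(n, lnp_range=(0, 10), seed=rng)
        kch = compute_kch(seq, 7.0, 293.0)
        spans = refsim.simulate_map(n, (4, 8), 3.0, rng)
        return refsim.project_rfu(truth, kch, spans, noise_sd=noise, seed=rng)

    def test_noise_free_roundtrip_exact(self):
        rs = self.make_refset()
        comp = rs.dataset.competent_residues
        kobs = kobs_from_lnp(
            rs.truth.subset(comp), rs.kch
        )
        model = model_rfu_table(kobs.as_dict(), rs.dataset)
        observed = np.array([p.rfu for p in rs.dataset.peptides])
        assert np.allclose(model, observed, atol=1e-15)

    def test_default_timepoints(self):
        rs = self.make_refset()
        assert rs.dataset.timepoints == (0.25, 1.0, 5.0, 20.0, 60.0, 240.0, 480.0)

    def test_unprotected_truth_near_saturation_at_long_time(self):
        rng = np.random.default_rng(8)
        n = 20
        seq = refsim.random_sequence(n, rng)
        truth = refsim.simulate_lnp(n, lnp_range=(0.0, 0.0), seed=rng)
        kch = compute_kch(seq, 7.0, 293.0)
        rs = refsim.project_rfu(truth, kch, [(1, 10), (10, 20)])
        final = [p.rfu[-1] for p in rs.dataset.peptides]
        assert min(final) > 0.99

    def test_noise_keeps_rfu_in_bounds(self):
        rs = self.make_refset(noise=0.2)
        for p in rs.dataset.peptides:
            assert all(0.0 <= v <= 1.0 for v in p.rfu)


class TestVariantLnp:
    def test_double_inversion_identity(self):
        truth = refsim.simulate_lnp(30, seed=9)
        twice = refsim.variant_lnp(refsim.variant_lnp(truth, "inverted"), "inverted")
        assert np.allclose(twice.values, truth.values)

    def test_randomised_is_permutation(self):
        truth = refsim.simulate_lnp(30, seed=9)
        rand = refsim.variant_lnp(truth, "randomised", seed=3)
        assert sorted(rand.values) == pytest.approx(sorted(truth.values))
        assert not np.array_equal(rand.values, truth.values)

    def test_constant_profile_inversion_fixed_point(self):
        from hdxsolver.forward_model import ProtectionVector
        p = ProtectionVector((1, 2, 3), np.array([5.0, 5.0, 5.0]))
        assert np.allclose(refsim.variant_lnp(p, "inverted").values, p.values)


class TestBuildLibrary:
    def test_count_occupancy_and_reproducibility(self):
        lib1 = refsim.build_library(n_datasets=4, seed=6)
        lib2 = refsim.build_library(n_datasets=4, seed=6)
        assert len(lib1) == 4
        for a, b in zip(lib1, lib2):
            assert [p.rfu for p in a.dataset.peptides] == [
                p.rfu for p in b.dataset.peptides
            ]
        for rs in lib1:
            assert rs.provenance.get("library_index") is not None
            assert len(rs.dataset.peptides) >= 2

    def test_emitted_peptides_passed_occupancy_filter(self):
        lib = refsim.build_library(n_datasets=3, seed=11)
        for rs in lib:
            assert rs.provenance["min_occupancy_at_filter"] >= 2.5

    def test_roundtrip_invariant_for_emitted_sets(self):
        lib = refsim.build_library(n_datasets=3, seed=13)
        for rs in lib:
            comp = rs.dataset.competent_residues
            kobs = kobs_from_lnp(rs.truth.subset(comp), rs.kch)
            model = model_rfu_table(kobs.as_dict(), rs.dataset)
            observed = np.array([p.rfu for p in rs.dataset.peptides])
            assert np.allclose(model, observed, atol=1e-15)
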