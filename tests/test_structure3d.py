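import math

import numpy as np
import pandas as pd
import pytest

from tf3dnet.core_io import GenomeStructure
from tf3dnet.structure3d import (consistent_pairs, crowding_strata, pe_score,
                                 qc_structure, sde, spatial_density,
                                 z_normalize_sde)
from conftest import sites_at_bins, string_structure


def _structure_from_models(models, chrom="chr1", compartment=None,
                           radius=None):
    n = models.shape[1]
    particles = pd.DataFrame({"chrom": [chrom] * n,
                              "start": np.arange(n) * 100_000})
    return GenomeStructure(np.asarray(models, dtype=float), particles,
                           radius=radius, compartment=compartment)


class TestQC:
    def test_identical_models_full_mask(self):
        struct = string_structure(n_particles=12, n_models=10)
        qc = qc_structure(struct)
        np.testing.assert_allclose(qc.rmsd, 0.0)
        assert qc.defined_mask.all()
        assert qc.coverage_fraction == 1.0

    def test_single_displacement_rmsd(self):
        # particle displaced by 2 radii in 1 of 10 models -> RMSD close to
        # 2/sqrt(10) relative to the reference model (the whole-model
        # superposition absorbs an O(1/n_particles) share of a single
        # displacement); well below 1 radius, so retained
        base = string_structure(n_particles=300, n_models=10)
        models = base.models.copy()
        models[5, 10, 1] += 2 * base.radius
        struct = _structure_from_models(models, radius=base.radius)
        qc = qc_structure(struct)
        assert qc.rmsd[10] == pytest.approx(2 / math.sqrt(10), rel=0.02)
        assert qc.defined_mask[10]

    def test_rmsd_above_one_radius_excluded(self):
        base = string_structure(n_particles=300, n_models=10)
        models = base.models.copy()
        # displacement of 1.2 * sqrt(10) radii in one model gives an RMSD
        # of 1.2 radii
        models[3, 7, 2] += 1.2 * math.sqrt(10) * base.radius
        struct = _structure_from_models(models, radius=base.radius)
        qc = qc_structure(struct)
        assert qc.rmsd[7] == pytest.approx(1.2, rel=0.05)
        assert not qc.defined_mask[7]

    def test_single_model_passes_all_with_warning(self):
        struct = string_structure(n_particles=5, n_models=1)
        with pytest.warns(UserWarning, match="single-model"):
            qc = qc_structure(struct)
        assert qc.defined_mask.all()

    def test_superposition_absorbs_rigid_motion(self, rng):
        base = string_structure(n_particles=15, n_models=4)
        models = base.models.copy()
        # rotate + translate one model rigidly: per-particle RMSD stays 0
        theta = 0.7
        R = np.array([[math.cos(theta), -math.sin(theta), 0],
                      [math.sin(theta), math.cos(theta), 0], [0, 0, 1]])
        models[2] = models[2] @ R.T + np.array([5.0, -3.0, 1.0])
        qc = qc_structure(_structure_from_models(models, radius=base.radius))
        np.testing.assert_allclose(qc.rmsd, 0.0, atol=1e-9)


class TestConsistentPairs:
    def test_requires_all_models(self):
        base = string_structure(n_particles=12, n_models=10)
        models = base.models.copy()
        # bring particles 0 and 8 close in 9 of 10 models only
        for m in range(1, 10):
            models[m, 8] = models[m, 0] + np.array([1.0, 0, 0])
        struct = _structure_from_models(models, radius=base.radius)
        qc = qc_structure(struct)
        qc.defined_mask[:] = True  # isolate the all-model proximity rule
        pairs = consistent_pairs(struct, qc, threshold=3.0)
        assert (0, 8) not in {tuple(p) for p in pairs.pairs}

    def test_sequential_exclusion(self):
        # straight line with step 0.2 radii: everything is spatially close,
        # but pairs <= 3 particles apart are excluded
        struct = string_structure(n_particles=8, n_models=2, step=0.2)
        qc = qc_structure(struct)
        got = {tuple(p) for p in consistent_pairs(struct, qc, 100.0).pairs}
        assert (0, 3) not in got
        assert (0, 4) in got

    def test_trans_mode_only_between_chromosomes(self):
        n = 6
        xyz = np.zeros((2 * n, 3))
        xyz[:n, 0] = np.arange(n)
        xyz[n:, 0] = np.arange(n)
        xyz[n:, 1] = 0.5
        particles = pd.DataFrame({
            "chrom": ["chr1"] * n + ["chr2"] * n,
            "start": list(np.arange(n) * 100_000) * 2})
        struct = GenomeStructure(np.stack([xyz, xyz]), particles, radius=0.5)
        qc = qc_structure(struct)
        trans = consistent_pairs(struct, qc, 3.0, mode="trans")
        chrom = struct.particles["chrom"].to_numpy()
        assert len(trans.pairs) > 0
        assert all(chrom[i] != chrom[j] for i, j in trans.pairs)
        cis = consistent_pairs(struct, qc, 3.0, mode="cis")
        assert all(chrom[i] == chrom[j] for i, j in cis.pairs)

    def test_threshold_monotonicity(self, rng):
        xyz = rng.normal(size=(40, 3)) * 2
        particles = pd.DataFrame({"chrom": ["chr1"] * 40,
                                  "start": np.arange(40) * 100_000})
        struct = GenomeStructure(np.stack([xyz, xyz + 0.01]), particles,
                                 radius=0.5)
        qc = qc_structure(struct)
        sets = [{tuple(p) for p in
                 consistent_pairs(struct, qc, t).pairs}
                for t in (1.5, 2.0, 3.0)]
        assert sets[0] <= sets[1] <= sets[2]


class TestSpatialDensity:
    def test_single_partner_inverse_cube(self):
        # particles 5 apart sequentially (beyond the 300-kb exclusion)
        struct = string_structure(n_particles=6, n_models=1, step=2.0)
        track = np.zeros(6)
        track[5] = 1.0
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            qc = qc_structure(struct)
        r = spatial_density(struct, qc, track).r
        assert r[0] == pytest.approx(1.0 / 10.0 ** 3)   # 5 steps of 2.0
        assert r[1] == pytest.approx(1.0 / 8.0 ** 3)    # 4 steps, admissible
        assert r[3] == pytest.approx(0.0)               # within exclusion

    def test_cubic_scaling(self, rng):
        xyz = rng.normal(size=(15, 3)) * 3
        particles = pd.DataFrame({"chrom": ["chr1"] * 15,
                                  "start": np.arange(15) * 100_000})
        s1 = GenomeStructure(np.stack([xyz, xyz]), particles, radius=0.5)
        s2 = GenomeStructure(np.stack([2 * xyz, 2 * xyz]), particles,
                             radius=1.0)
        track = rng.random(15)
        qc = qc_structure(s1)
        qc.defined_mask[:] = True
        r1 = spatial_density(s1, qc, track).r
        r2 = spatial_density(s2, qc, track).r
        np.testing.assert_allclose(r2, r1 / 8.0, rtol=1e-9)

    def test_matches_brute_force(self, rng):
        n = 10
        xyz = rng.normal(size=(n, 3)) * 4
        models = np.stack([xyz, xyz + rng.normal(size=(n, 3)) * 0.05])
        particles = pd.DataFrame({"chrom": ["chr1"] * n,
                                  "start": np.arange(n) * 100_000})
        struct = GenomeStructure(models, particles, radius=0.5)
        qc = qc_structure(struct)
        qc.defined_mask[:] = True
        track = rng.random(n)
        r = spatial_density(struct, qc, track).r
        # brute force: average over models of sum_j n_j / d^3, |i-j| > 3
        expected = np.zeros(n)
        for i in range(n):
            for m in range(2):
                for j in range(n):
                    if abs(i - j) > 3:
                        d = np.linalg.norm(models[m, i] - models[m, j])
                        expected[i] += track[j] / d ** 3 / 2
        np.testing.assert_allclose(r, expected, rtol=1e-9)

    def test_rotational_invariance(self, rng):
        n = 20
        xyz = rng.normal(size=(n, 3)) * 3
        models = np.stack([xyz, xyz + 0.01])
        particles = pd.DataFrame({"chrom": ["chr1"] * n,
                                  "start": np.arange(n) * 100_000})
        comp = np.array(["A"] * 10 + ["B"] * 10, dtype=object)
        s1 = GenomeStructure(models.copy(), particles, radius=0.5,
                             compartment=comp)
        theta = 1.1
        R = np.array([[math.cos(theta), -math.sin(theta), 0],
                      [math.sin(theta), math.cos(theta), 0], [0, 0, 1]])
        s2 = GenomeStructure(models @ R.T + 7.0, particles, radius=0.5,
                             compartment=comp)
        track = rng.random(n)
        qc1, qc2 = qc_structure(s1), qc_structure(s2)
        np.testing.assert_allclose(spatial_density(s1, qc1, track).r,
                                   spatial_density(s2, qc2, track).r,
                                   rtol=1e-9)
        np.testing.assert_allclose(
            sde(s1, qc1, track, n_perm=10, seed=4).sde,
            sde(s2, qc2, track, n_perm=10, seed=4).sde, rtol=1e-6, atol=1e-9)


class TestSDE:
    def _structure(self, rng, n=30):
        xyz = rng.normal(size=(n, 3)) * 2
        particles = pd.DataFrame({"chrom": ["chr1"] * n,
                                  "start": np.arange(n) * 100_000})
        comp = np.array(["A", "B"] * (n // 2), dtype=object)
        return GenomeStructure(np.stack([xyz, xyz + 0.01]), particles,
                               radius=0.5, compartment=comp)

    def test_uniform_track_gives_zero(self, rng):
        struct = self._structure(rng)
        qc = qc_structure(struct)
        res = sde(struct, qc, np.ones(30), n_perm=7, seed=0)
        np.testing.assert_allclose(res.sde[np.isfinite(res.sde)], 0.0,
                                   atol=1e-9)

    def test_seed_determinism(self, rng):
        struct = self._structure(rng)
        qc = qc_structure(struct)
        track = rng.random(30)
        a = sde(struct, qc, track, n_perm=20, seed=9).sde
        b = sde(struct, qc, track, n_perm=20, seed=9).sde
        np.testing.assert_array_equal(a, b)

    def test_orientation_switch_flips_sign(self, rng):
        struct = self._structure(rng)
        qc = qc_structure(struct)
        track = rng.random(30)
        a = sde(struct, qc, track, n_perm=20, seed=9).sde
        b = sde(struct, qc, track, n_perm=20, seed=9,
                orientation="enrichment").sde
        np.testing.assert_allclose(a, -b, atol=1e-9)


class TestZNormalize:
    def test_reference_quartile_already_standard(self, rng):
        track = np.arange(100.0)
        sde_vals = rng.normal(size=100)
        ref = sde_vals[:25]
        sde_vals[:25] = (ref - ref.mean()) / ref.std()
        out = z_normalize_sde(sde_vals, track)
        np.testing.assert_allclose(out[:25].mean(), 0.0, atol=1e-9)
        np.testing.assert_allclose(out[:25].std(), 1.0, atol=1e-9)

    def test_affine_equivariance(self, rng):
        # the reference mean/SD are re-estimated from the input, so a
        # global shift cancels and a global scaling cancels too
        track = rng.random(100)
        sde_vals = rng.normal(size=100)
        base = z_normalize_sde(sde_vals, track)
        np.testing.assert_allclose(z_normalize_sde(sde_vals + 3.0, track),
                                   base, atol=1e-9)
        np.testing.assert_allclose(z_normalize_sde(sde_vals * 2.0, track),
                                   base, atol=1e-9)

    def test_hand_computed_standardization(self):
        track = np.concatenate([np.zeros(25), np.ones(75)])
        vals = np.concatenate([np.array([0.0, 2.0] * 12 + [1.0]),
                               np.full(75, 5.0)])
        out = z_normalize_sde(vals, track)
        ref = vals[:25]
        np.testing.assert_allclose(out, (vals - ref.mean()) / ref.std())

    def test_zero_reference_sd_raises(self):
        with pytest.raises(ValueError, match="zero SD"):
            z_normalize_sde(np.ones(40), np.arange(40.0))


class TestCrowdingStrata:
    def _pairs_all(self, n):
        from tf3dnet.structure3d import ProximityPairs
        pairs = np.array([(i, j) for i in range(n) for j in range(i + 1, n)])
        return ProximityPairs(3.0, "all", pairs, n)

    def test_equal_group_sizes(self):
        n = 100
        pairs = self._pairs_all(n)
        particle_idx = np.arange(n)
        comp = np.array(["A"] * n, dtype=object)
        strata = crowding_strata(pairs, particle_idx, comp, n_groups=5)
        assert np.bincount(strata).tolist() == [20] * 5

    def test_tied_crowding_still_equal_groups(self):
        n = 50
        pairs = self._pairs_all(n)
        comp = np.array(["A"] * n, dtype=object)
        strata = crowding_strata(pairs, np.arange(n), comp, n_groups=5)
        assert np.bincount(strata).tolist() == [10] * 5

    def test_configurable_group_count(self):
        n = 100
        pairs = self._pairs_all(n)
        comp = np.array(["A"] * n, dtype=object)
        for g in (10, 20):
            strata = crowding_strata(pairs, np.arange(n), comp, n_groups=g)
            assert np.bincount(strata).tolist() == [100 // g] * g


class TestPE:
    def test_pe_zero_when_null_is_identity(self):
        # five pooled sites in one compartment split into five crowding
        # groups of one: every stratum is a singleton, the permutation is
        # the identity, so Exp == Obs exactly and PE == 0
        struct = string_structure(n_particles=12, n_models=2, step=1.0,
                                  compartment=np.array(["A"] * 12,
                                                       dtype=object))
        a = sites_at_bins([0, 5, 11], "A", bin_size=100_000)
        b = sites_at_bins([1, 7], "B", bin_size=100_000)
        qc = qc_structure(struct)
        pe, p, obs, exp = pe_score(a, b, struct, qc, n_perm=20, seed=0,
                                   threshold=100.0)
        assert obs == exp
        assert pe == pytest.approx(0.0, abs=1e-12)

    def test_pe_is_log2_of_obs_over_exp(self, rng):
        from tf3dnet.synthetic import SyntheticSpec, TFSpec, make_structure
        spec = SyntheticSpec(seed=8, n_chroms=1,
                             tf_specs=(TFSpec("A", 40), TFSpec("B", 40),
                                       TFSpec("C", 40)),
                             planted_pairs=())
        struct, sets = make_structure(spec)
        qc = qc_structure(struct)
        pe, p, obs, exp = pe_score(sets[0], sets[1], struct, qc,
                                   all_site_sets=sets, n_perm=30, seed=2)
        if obs > 0 and exp > 0:
            assert pe == pytest.approx(math.log2(obs / exp))

    def test_trans_mode_single_chromosome_raises(self):
        struct = string_structure(n_particles=10, n_models=2,
                                  compartment=np.array(["A"] * 10,
                                                       dtype=object))
        a = sites_at_bins([0, 5], "A", bin_size=100_000)
        b = sites_at_bins([1, 6], "B", bin_size=100_000)
        qc = qc_structure(struct)
        with pytest.raises(ValueError, match="trans"):
            pe_score(a, b, struct, qc, mode="trans", n_perm=5, seed=0)

    def test_homotypic_diagonal_uses_unordered_pairs(self):
        # 2 sites in particles 0 and 6 (proximal under a huge threshold):
        # exactly one unordered pair
        struct = string_structure(n_particles=8, n_models=2, step=1.0,
                                  compartment=np.array(["A"] * 8,
                                                       dtype=object))
        a = sites_at_bins([0, 6], "A", bin_size=100_000)
        qc = qc_structure(struct)
        pe, p, obs, exp = pe_score(a, a, struct, qc, n_perm=5, seed=0,
                                   threshold=100.0)
        assert obs == 1.0
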