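"""TM-score, LDDT and neighbor-density classification."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from scdistill import (
    BackboneStructure, lddt, lddt_from_distance_matrices, make_backbone,
    neighbor_density_class, perturb_backbone, tm_d0, tm_score,
    LDDT_TOLERANCES,
)


def brute_force_lddt(model_xyz, ref_xyz, radius=15.0, tolerances=LDDT_TOLERANCES):
    """Independent O(n^2) loop re-implementation of C-alpha LDDT."""
    n = len(ref_xyz)
    per_res = []
    for i in range(n):
        fracs = []
        pairs = [j for j in range(n)
                 if j != i and np.linalg.norm(ref_xyz[i] - ref_xyz[j]) < radius]
        if not pairs:
            per_res.append(np.nan)
            continue
        for tol in tolerances:
            kept = 0
            for j in pairs:
                dm = np.linalg.norm(model_xyz[i] - model_xyz[j])
                dr = np.linalg.norm(ref_xyz[i] - ref_xyz[j])
                if abs(dm - dr) < tol:
                    kept += 1
            fracs.append(kept / len(pairs))
        per_res.append(sum(fracs) / len(fracs))
    per_res = np.array(per_res)
    return float(np.nanmean(per_res)), per_res


def displaced_by_d0_pair(n_quartets=24):
    """Reference in the z=0 plane; model displaced +-d0 along z in a pattern
    whose cross-covariance with the reference vanishes, so the optimal
    superposition is the identity and every aligned distance equals d0."""
    L = 4 * n_quartets
    d0 = tm_d0(L)
    ref, dz = [], []
    for q in range(n_quartets):
        a = 5.0 + 3.0 * q
        ref += [(a, 0, 0), (-a, 0, 0), (0, a, 0), (0, -a, 0)]
        dz += [d0, d0, -d0, -d0]
    ref = np.array(ref, float)
    model = ref + np.outer(dz, [0, 0, 1.0])
    return (BackboneStructure(ca_coords=model),
            BackboneStructure(ca_coords=ref))


class TestTMScore:
    def test_identical_structures_score_one(self, coil20):
        assert tm_score(coil20, coil20) == pytest.approx(1.0, abs=1e-12)

    def test_d0_formula_at_length_100(self):
        assert tm_d0(100) == pytest.approx(1.24 * 85.0 ** (1 / 3) - 1.8, abs=1e-12)
        assert tm_d0(100) == pytest.approx(3.6521, abs=1e-4)

    def test_d0_clamped_for_short_chains(self):
        for L in (1, 15, 21):
            assert tm_d0(L) == 0.5
        assert tm_d0(22) > 0.5

    def test_uniform_d0_displacement_gives_exactly_half(self):
        model, ref = displaced_by_d0_pair()
        assert tm_score(model, ref) == pytest.approx(0.5, abs=1e-12)

    def test_invariant_under_rigid_motion(self):
        rng = np.random.default_rng(3)
        ref = make_backbone(25, "random_coil", rng)
        model = perturb_backbone(ref, 1.0, rng)
        base = tm_score(model, ref)
        for seed in range(5):
            r = np.random.default_rng(seed)
            R = Rotation.random(rng=r).as_matrix()
            moved = model.transformed(R, r.normal(scale=20, size=3))
            assert tm_score(moved, ref) == pytest.approx(base, abs=1e-9)

    def test_symmetric_under_swap_at_equal_lengths(self):
        rng = np.random.default_rng(4)
        a = make_backbone(30, "random_coil", rng)
        b = perturb_backbone(a, 1.5, rng)
        assert tm_score(a, b) == pytest.approx(tm_score(b, a), abs=1e-9)

    def test_correspondence_validation(self, coil20):
        with pytest.raises(ValueError, match="non-empty"):
            tm_score(coil20, coil20, correspondence=[])
        with pytest.raises(ValueError, match="out of range"):
            tm_score(coil20, coil20, correspondence=[(0, 25)])
        short = make_backbone(10, "extended")
        with pytest.raises(ValueError, match="equal lengths"):
            tm_score(short, coil20)


class TestLDDT:
    def test_identical_structures_score_one(self, coil20):
        g, per = lddt(coil20, coil20)
        assert g == 1.0
        assert np.all(per[np.isfinite(per)] == 1.0)

    def test_uniform_distance_shift_brackets_tolerances(self):
        """+1.5 A on every pair distance fails tolerances 0.5/1, passes 2/4."""
        rng = np.random.default_rng(5)
        ref = make_backbone(15, "random_coil", rng)
        dr = cdist(ref.ca_coords, ref.ca_coords)
        dm = dr + 1.5 * (1 - np.eye(len(dr)))
        g, per = lddt_from_distance_matrices(dm, dr)
        assert g == pytest.approx(0.5, abs=1e-12)
        assert np.all(np.abs(per[np.isfinite(per)] - 0.5) < 1e-12)

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            n = int(rng.integers(5, 31))
            ref = make_backbone(n, "random_coil", rng)
            model = perturb_backbone(ref, float(rng.uniform(0.2, 3.0)), rng)
            g, per = lddt(model, ref)
            g_bf, per_bf = brute_force_lddt(model.ca_coords, ref.ca_coords)
            assert g == pytest.approx(g_bf, abs=1e-12)
            np.testing.assert_allclose(per, per_bf, atol=1e-12)

    def test_superposition_free(self):
        rng = np.random.default_rng(7)
        ref = make_backbone(20, "random_coil", rng)
        model = perturb_backbone(ref, 1.0, rng)
        base, _ = lddt(model, ref)
        R = Rotation.random(rng=rng).as_matrix()
        moved = model.transformed(R, np.array([30.0, -10.0, 5.0]))
        g, _ = lddt(moved, ref)
        assert g == pytest.approx(base, abs=1e-9)

    def test_global_equals_mean_of_per_residue(self):
        rng = np.random.default_rng(8)
        ref = make_backbone(25, "random_coil", rng)
        model = perturb_backbone(ref, 2.0, rng)
        g, per = lddt(model, ref)
        assert g == pytest.approx(float(np.nanmean(per)), abs=1e-15)

    def test_residue_with_no_pairs_excluded(self, caplog):
        # two clusters >15 A apart plus one far-isolated residue
        coords = np.array([[0, 0, 0], [3.8, 0, 0], [7.6, 0, 0],
                           [500.0, 0, 0]])
        ref = BackboneStructure(ca_coords=coords)
        g, per = lddt(ref, ref)
        assert np.isnan(per[3]) and g == 1.0

    def test_fewer_than_two_residues_is_an_error(self):
        one = BackboneStructure(ca_coords=[[0, 0, 0]])
        with pytest.raises(ValueError):
            lddt(one, one)


class TestNeighborDensity:
    def test_isolated_residue_is_surface(self):
        s = BackboneStructure(ca_coords=[[0, 0, 0], [100, 0, 0], [200, 0, 0]])
        nc = neighbor_density_class(s, 0)
        assert nc.label == "surface" and nc.n_neighbors == 0

    def test_dense_cluster_is_core(self):
        # 30 residues inside a 4.5 A-radius ball: all pairwise within 10 A
        rng = np.random.default_rng(9)
        pts = rng.uniform(-2.6, 2.6, size=(30, 3))
        s = BackboneStructure(ca_coords=pts)
        for i in range(30):
            nc = neighbor_density_class(s, i)
            assert nc.label == "core" and nc.n_neighbors == 29

    def test_exactly_twenty_neighbors_is_intermediate(self):
        rng = np.random.default_rng(10)
        near = rng.normal(size=(20, 3))
        near = 5.0 * near / np.linalg.norm(near, axis=1, keepdims=True)
        far = np.array([[40.0 + 30 * k, 0, 0] for k in range(4)])
        coords = np.vstack([[0.0, 0, 0], near, far])
        nc = neighbor_density_class(BackboneStructure(ca_coords=coords), 0)
        assert nc.n_neighbors == 20 and nc.label == "intermediate"

    def test_out_of_range_index_is_an_error(self, coil20):
        with pytest.raises(IndexError):
            neighbor_density_class(coil20, 20)
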