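"""Synthetic backbones, oracles and the toy design task."""

import numpy as np
import pytest

from scdistill import (
    lddt, make_backbone, make_design_task, make_oracle, perturb_backbone,
    recovery, tm_score,
)
from scdistill.synthetic import hydropathy_oracle


class TestMakeBackbone:
    @pytest.mark.parametrize("kind", ["helix", "extended", "random_coil"])
    def test_consecutive_ca_distances_in_range(self, kind):
        bb = make_backbone(25, kind, np.random.default_rng(0))
        d = np.linalg.norm(np.diff(bb.ca_coords, axis=0), axis=1)
        assert np.all(d >= 2.9) and np.all(d <= 4.1)

    def test_helix_spacing_near_canonical(self):
        bb = make_backbone(20, "helix")
        d = np.linalg.norm(np.diff(bb.ca_coords, axis=0), axis=1)
        np.testing.assert_allclose(d, 3.8, atol=0.15)

    def test_deterministic_under_seed(self):
        a = make_backbone(15, "random_coil", np.random.default_rng(5))
        b = make_backbone(15, "random_coil", np.random.default_rng(5))
        np.testing.assert_array_equal(a.ca_coords, b.ca_coords)

    def test_helix_and_extended_folds_differ(self):
        h = make_backbone(30, "helix")
        e = make_backbone(30, "extended")
        assert tm_score(h, e) < 1.0

    def test_self_avoidance(self):
        bb = make_backbone(40, "random_coil", np.random.default_rng(1))
        from scipy.spatial.distance import pdist

        d = pdist(bb.ca_coords)
        # non-adjacent pairs stay above the clash threshold
        assert np.sort(d)[: 39].min() >= 3.3  # adjacent steps are 3.8

    def test_too_short_chain_rejected(self):
        with pytest.raises(ValueError):
            make_backbone(1)


class TestPerturbBackbone:
    def test_zero_magnitude_keeps_metrics_at_one(self, coil20):
        rng = np.random.default_rng(0)
        same = perturb_backbone(coil20, 0.0, rng)
        assert tm_score(same, coil20) == pytest.approx(1.0, abs=1e-12)
        assert lddt(same, coil20)[0] == pytest.approx(1.0)

    def test_moderate_noise_degrades_lddt(self, coil20):
        pert = perturb_backbone(coil20, 2.0, np.random.default_rng(1))
        assert lddt(pert, coil20)[0] < 1.0

    def test_tm_decreases_with_magnitude_in_expectation(self):
        rng = np.random.default_rng(2)
        base = make_backbone(30, "random_coil", rng)
        means = []
        for mag in (0.5, 1.0, 2.0, 4.0):
            vals = [tm_score(perturb_backbone(base, mag,
                                              np.random.default_rng(s)), base)
                    for s in range(8)]
            means.append(np.mean(vals))
        assert all(a > b for a, b in zip(means, means[1:]))


class TestOracle:
    def test_deterministic(self, oracle):
        assert oracle.score("A" * 30) == oracle.score("A" * 30)

    def test_scalar_is_mean_of_track(self, oracle):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        assert oracle.score(seq) == pytest.approx(
            float(oracle.score_track(seq).mean()))

    def test_single_edit_changes_scores_only_within_window(self, oracle):
        seq = "A" * 41
        edited = seq[:20] + "W" + seq[21:]
        a = oracle.score_track(seq)
        b = oracle.score_track(edited)
        changed = np.flatnonzero(~np.isclose(a, b))
        assert changed.size > 0
        assert changed.min() >= 20 - oracle.window
        assert changed.max() <= 20 + oracle.window

    def test_scores_bounded_on_many_random_sequences(self, oracle):
        rng = np.random.default_rng(3)
        for _ in range(200):
            L = int(rng.integers(5, 80))
            seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=L))
            track = oracle.score_track(seq)
            assert np.all(track > 0) and np.all(track < 1)

    def test_hydropathy_oracle_is_fixed_and_interpretable(self):
        a, b = hydropathy_oracle(), hydropathy_oracle()
        np.testing.assert_array_equal(a.coefficients, b.coefficients)
        # poly-isoleucine (most hydrophobic) scores above poly-arginine (least)
        assert a.score("I" * 30) > a.score("R" * 30)


class TestDesignTask:
    def test_noise_free_task_is_solved_by_rule_lookup(self):
        task = make_design_task(5, noise=0.0, rng=np.random.default_rng(0))
        for i in range(len(task)):
            assert recovery(task.rule_lookup_sequence(i),
                            task.sequences[i]) == 100.0

    def test_full_noise_drops_rule_lookup_to_chance(self):
        task = make_design_task(30, noise=1.0, rng=np.random.default_rng(1))
        recs = [recovery(task.rule_lookup_sequence(i), task.sequences[i])
                for i in range(len(task))]
        # chance level is 100/20 = 5 percent
        assert abs(np.mean(recs) - task.chance_recovery) < 3.0

    def test_mask_spans_are_contiguous_and_in_range(self):
        task = make_design_task(10, noise=0.2, rng=np.random.default_rng(2),
                                mask_fraction=0.25)
        for (lo, hi), seq in zip(task.mask_spans, task.sequences):
            assert 0 <= lo < hi <= len(seq)
            assert hi - lo == max(1, round(0.25 * len(seq)))

    def test_features_are_rotation_invariant(self):
        from scipy.spatial.transform import Rotation

        from scdistill import backbone_features

        task = make_design_task(2, rng=np.random.default_rng(3))
        bb = task.backbones[0]
        R = Rotation.from_rotvec([0.5, 0.4, -0.3]).as_matrix()
        moved = bb.transformed(R, np.array([10.0, -5.0, 3.0]))
        np.testing.assert_allclose(backbone_features(moved),
                                   backbone_features(bb), atol=1e-9)
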