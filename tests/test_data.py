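"""Dataset records, curation operations and IO."""

import dataclasses

import numpy as np
import pytest

from scdistill import (
    DatasetManifest, ScoredSequence, UnscoredSequence, augment_perturb,
    balance_filter, crop_sequence, filter_by_similarity,
    generate_synthetic_scored, read_jsonl, sampling_weights,
    sequence_similarity, write_jsonl,
)


def nw_identity(a: str, b: str) -> float:
    """Textbook global-alignment identity oracle (match=1, mismatch/gap=0)."""
    n, m = len(a), len(b)
    dp = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            dp[i, j] = max(dp[i - 1, j - 1] + (a[i - 1] == b[j - 1]),
                           dp[i - 1, j], dp[i, j - 1])
    return 100.0 * dp[n, m] / n


class TestScoredSequence:
    def test_requires_at_least_one_score(self):
        with pytest.raises(ValueError, match="at least one"):
            ScoredSequence(id="x", sequence="ACD")

    def test_scores_must_be_strictly_inside_unit_interval(self):
        with pytest.raises(ValueError):
            ScoredSequence(id="x", sequence="ACD", scalar_score=1.0)
        with pytest.raises(ValueError):
            ScoredSequence(id="x", sequence="ACD", residue_scores=[0.5, 0.0, 0.5])

    def test_residue_scores_length_checked(self):
        with pytest.raises(ValueError, match="length"):
            ScoredSequence(id="x", sequence="ACD", residue_scores=[0.5, 0.5])

    def test_illegal_residues_rejected(self):
        with pytest.raises(ValueError, match="illegal"):
            ScoredSequence(id="x", sequence="ACB", scalar_score=0.5)


class TestSimilarityFilter:
    def test_exact_duplicate_removed_at_any_threshold(self):
        rec = ScoredSequence(id="a", sequence="ACDEFGHIKL", scalar_score=0.5)
        assert filter_by_similarity([rec], ["ACDEFGHIKL"], threshold=100.0) == []
        assert filter_by_similarity([rec], ["ACDEFGHIKL"], threshold=40.0) == []

    def test_disjoint_kmer_candidate_retained(self):
        rec = ScoredSequence(id="a", sequence="AAAAAAAAAA", scalar_score=0.5)
        kept = filter_by_similarity([rec], ["WWWWWWWWWW"], threshold=40.0)
        assert kept == [rec]

    def test_empty_candidates_give_empty_result(self):
        assert filter_by_similarity([], ["ACD"], threshold=40.0) == []

    def test_identity_method_matches_dp_oracle(self):
        rng = np.random.default_rng(0)
        alphabet = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(20):
            a = "".join(rng.choice(list(alphabet), size=12))
            b = list(a)
            for i in rng.choice(12, size=6, replace=False):
                b[i] = "W" if a[i] != "W" else "Y"
            b = "".join(b)
            ours = sequence_similarity(a, b, method="identity")
            assert ours == pytest.approx(nw_identity(a, b))

    def test_half_substituted_sequence_filter_decision(self):
        # 6 of 12 positions replaced by letters absent from the original:
        # global identity is 50%, so threshold 40 removes, threshold 60 keeps
        hold = "ACDEFGHIKLMN"
        cand = "WCWEWGWIWLWN"
        assert nw_identity(cand, hold) == pytest.approx(50.0)
        rec = ScoredSequence(id="c", sequence=cand, scalar_score=0.5)
        assert filter_by_similarity([rec], [hold], 40.0, method="identity") == []
        assert filter_by_similarity([rec], [hold], 60.0, method="identity") == [rec]


class TestCrop:
    def test_long_record_cropped_to_window(self):
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=600))
        scores = rng.uniform(0.1, 0.9, size=600)
        rec = ScoredSequence(id="x", sequence=seq, residue_scores=scores)
        out = crop_sequence(rec, 500, np.random.default_rng(2))
        assert len(out.sequence) == 500
        start = seq.index(out.sequence)
        np.testing.assert_array_equal(out.residue_scores, scores[start:start + 500])

    def test_short_record_unchanged(self):
        rec = ScoredSequence(id="x", sequence="ACDE", scalar_score=0.3)
        assert crop_sequence(rec, 500) is rec

    def test_deterministic_under_seed(self):
        seq = "ACDEFGHIKL" * 100
        rec = ScoredSequence(id="x", sequence=seq, scalar_score=0.4)
        a = crop_sequence(rec, 300, np.random.default_rng(7))
        b = crop_sequence(rec, 300, np.random.default_rng(7))
        assert a.sequence == b.sequence


class TestAugment:
    def test_permute_conserves_residue_multiset(self):
        rec = ScoredSequence(id="x", sequence="ACDEFG", scalar_score=0.5)
        out = augment_perturb(rec, np.random.default_rng(0),
                              op="segment_permute", intensity=1.0)
        assert isinstance(out, UnscoredSequence)
        assert sorted(out.sequence) == sorted(rec.sequence)

    def test_zero_intensity_is_a_precondition_error(self):
        rec = ScoredSequence(id="x", sequence="ACDEFG", scalar_score=0.5)
        with pytest.raises(ValueError, match="intensity"):
            augment_perturb(rec, np.random.default_rng(0), intensity=0.0)

    def test_replace_hamming_distance_bounded_by_segment(self):
        import math

        rng = np.random.default_rng(3)
        rec = ScoredSequence(id="x", sequence="ACDEFGHIKLMNPQRSTVWY" * 2,
                             scalar_score=0.5)
        intensity = 0.3
        bound = math.ceil(intensity * len(rec.sequence))
        for _ in range(100):
            out = augment_perturb(rec, rng, op="segment_replace",
                                  intensity=intensity)
            ham = sum(a != b for a, b in zip(out.sequence, rec.sequence))
            assert ham <= bound
            assert len(out.sequence) == len(rec.sequence)

    def test_length_one_sequence_returned_unchanged_with_warning(self):
        rec = ScoredSequence(id="x", sequence="A", scalar_score=0.5)
        with pytest.warns(UserWarning):
            out = augment_perturb(rec, np.random.default_rng(0))
        assert out.sequence == "A"


class TestBalanceAndWeights:
    def _records(self, scores):
        return [ScoredSequence(id=f"r{i}", sequence="ACDEFG", scalar_score=s)
                for i, s in enumerate(scores)]

    def test_all_below_cutoff_kept(self):
        recs = self._records([0.1, 0.2, 0.3])
        kept, rep = balance_filter(recs, 0.5, 0.0, np.random.default_rng(0))
        assert kept == recs and rep["n_after"] == 3

    def test_zero_keep_fraction_drops_everything_above(self):
        recs = self._records([0.1, 0.2, 0.8, 0.9])
        kept, _ = balance_filter(recs, 0.5, 0.0, np.random.default_rng(0))
        assert [r.scalar_score for r in kept] == [0.1, 0.2]

    def test_equalizing_keep_fraction_balances_mass(self):
        # 80% of records above the cutoff; keeping a quarter of them
        # equalizes the above/below mass in expectation
        rng = np.random.default_rng(4)
        scores = np.concatenate([rng.uniform(0.05, 0.45, 200),
                                 rng.uniform(0.55, 0.95, 800)])
        recs = self._records(scores)
        fracs = []
        for seed in range(10):
            kept, _ = balance_filter(recs, 0.5, 0.25,
                                     np.random.default_rng(seed))
            above = sum(r.scalar_score >= 0.5 for r in kept)
            fracs.append(above / len(kept))
        assert abs(np.mean(fracs) - 0.5) < 0.05

    def test_single_bin_gives_uniform_weights(self):
        recs = self._records([0.501, 0.502, 0.503])
        w = sampling_weights(recs)
        np.testing.assert_allclose(w, 1 / 3)

    def test_ninety_ten_split_gives_one_to_nine_ratio(self):
        recs = self._records([0.15] * 90 + [0.85] * 10)
        w = sampling_weights(recs)
        assert w[95] / w[0] == pytest.approx(9.0)
        assert w.sum() == pytest.approx(1.0)


class TestSyntheticScored:
    def test_constant_scorer(self):
        recs = generate_synthetic_scored(5, lambda s: 0.3,
                                         rng=np.random.default_rng(0))
        assert len(recs) == 5
        assert all(r.scalar_score == 0.3 for r in recs)

    def test_deterministic_under_seed(self, oracle):
        a = generate_synthetic_scored(10, oracle, rng=np.random.default_rng(1))
        b = generate_synthetic_scored(10, oracle, rng=np.random.default_rng(1))
        assert [(r.id, r.sequence, r.scalar_score) for r in a] == \
               [(r.id, r.sequence, r.scalar_score) for r in b]

    def test_out_of_range_scorer_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            generate_synthetic_scored(1, lambda s: 1.5,
                                      rng=np.random.default_rng(0))

    def test_oracle_scores_span_many_bins(self, oracle):
        recs = generate_synthetic_scored(1000, oracle,
                                         rng=np.random.default_rng(2))
        hist = DatasetManifest(recs).bin_histogram()
        assert np.count_nonzero(hist) >= 10


class TestIO:
    def test_jsonl_round_trip(self, tmp_path, tiny_dataset):
        path = tmp_path / "d.jsonl"
        write_jsonl(tiny_dataset, path)
        again = read_jsonl(path)
        assert [r.id for r in again] == [r.id for r in tiny_dataset]
        assert [r.sequence for r in again] == [r.sequence for r in tiny_dataset]

    def test_manifest_histogram_sums_to_record_count(self, tiny_dataset):
        m = DatasetManifest(tiny_dataset)
        assert m.bin_histogram().sum() == len(tiny_dataset)

    def test_per_residue_manifest_sums_to_residue_count(self, oracle):
        recs = generate_synthetic_scored(
            10, oracle.score_track, rng=np.random.default_rng(3),
            per_residue=True)
        m = DatasetManifest(recs, kind="per_residue")
        assert m.bin_histogram().sum() == sum(len(r.sequence) for r in recs)
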