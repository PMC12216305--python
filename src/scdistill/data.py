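"""Scored-sequence records and dataset curation.

Implements the curation pipeline used to build sequence -> confidence-score
training sets: similarity filtering against held-out splits, random
cropping to a maximum length, sequence-perturbation augmentation, score
balancing, inverse-frequency sampling weights, and synthetic scored-set
generation.  Datasets are exchanged as JSONL
(``{"id", "sequence", "scalar_score", "residue_scores", "provenance"}``),
CSV, and FASTA; a manifest records per-bin histograms.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio import SeqIO
from Bio.Align import PairwiseAligner
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .binning import ScoreBinning, discretize_score

__all__ = [
    "AA_ALPHABET",
    "ScoredSequence",
    "UnscoredSequence",
    "DatasetManifest",
    "filter_by_similarity",
    "sequence_similarity",
    "crop_sequence",
    "augment_perturb",
    "balance_filter",
    "sampling_weights",
    "generate_synthetic_scored",
    "read_jsonl",
    "write_jsonl",
    "write_csv",
    "read_fasta",
    "write_fasta",
    "plddt_to_unit",
    "plddt_from_unit",
]

#: The 20 standard amino acids; 'X' additionally allowed as unknown.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_VALID = set(AA_ALPHABET) | {"X"}


def _check_scores(scores, what: str) -> None:
    arr = np.asarray(scores, float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0.0) or np.any(arr >= 1.0):
        raise ValueError(f"{what} must lie strictly inside (0, 1)")


@dataclasses.dataclass
class ScoredSequence:
    """An amino-acid sequence with a scalar and/or per-residue score in (0, 1)."""

    id: str
    sequence: str
    scalar_score: Optional[float] = None
    residue_scores: Optional[np.ndarray] = None
    provenance: str = "original"

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError("sequence must be non-empty")
        bad = [c for c in self.sequence if c not in _VALID]
        if bad:
            raise ValueError(f"illegal residue(s) {sorted(set(bad))} in {self.id}")
        if self.scalar_score is None and self.residue_scores is None:
            raise ValueError("at least one of scalar_score / residue_scores required")
        if self.scalar_score is not None:
            _check_scores(self.scalar_score, "scalar_score")
            self.scalar_score = float(self.scalar_score)
        if self.residue_scores is not None:
            self.residue_scores = np.asarray(self.residue_scores, float)
            if len(self.residue_scores) != len(self.sequence):
                raise ValueError("residue_scores length must equal sequence length")
            _check_scores(self.residue_scores, "residue_scores")

    def mean_score(self) -> float:
        """Scalar summary: the scalar score, else the mean residue score."""
        if self.scalar_score is not None:
            return self.scalar_score
        return float(self.residue_scores.mean())


@dataclasses.dataclass
class UnscoredSequence:
    """A perturbed sequence awaiting a score from an external scorer."""

    id: str
    sequence: str
    provenance: str = "augmented"


@dataclasses.dataclass
class DatasetManifest:
    """Records plus bookkeeping: per-bin histogram and provenance counts."""

    records: List[ScoredSequence]
    binning: ScoreBinning = ScoreBinning()
    kind: str = "scalar"  # "scalar": histogram over records; "per_residue": over residues

    def bin_histogram(self) -> np.ndarray:
        counts = np.zeros(self.binning.n_bins, dtype=int)
        for rec in self.records:
            if self.kind == "per_residue" and rec.residue_scores is not None:
                labels = discretize_score(rec.residue_scores, self.binning)
                np.add.at(counts, labels, 1)
            else:
                counts[discretize_score(rec.mean_score(), self.binning)] += 1
        return counts

    def provenance_counts(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for rec in self.records:
            out[rec.provenance] = out.get(rec.provenance, 0) + 1
        return out

    def to_dict(self) -> dict:
        return {
            "n_records": len(self.records),
            "kind": self.kind,
            "n_bins": self.binning.n_bins,
            "bin_histogram": self.bin_histogram().tolist(),
            "provenance": self.provenance_counts(),
        }


# ---------------------------------------------------------------------------
# similarity filtering

def _kmers(seq: str, k: int) -> set:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def sequence_similarity(query: str, target: str, method: str = "kmer", k: int = 3) -> float:
    """Percent similarity of ``query`` to ``target``.

    ``kmer``: fraction of the query's k-mers (k=3) present in the target's
    k-mer set, times 100 — a cheap containment proxy that is exact for
    identical sequences.  ``identity``: global Needleman-Wunsch identity
    (match=1, mismatch=0, gap=0) normalized by query length, for short
    sequences where the exact value matters.
    """
    if method == "identity":
        aligner = PairwiseAligner(
            mode="global", match_score=1.0, mismatch_score=0.0,
            open_gap_score=0.0, extend_gap_score=0.0,
        )
        return 100.0 * float(aligner.score(query, target)) / len(query)
    if method != "kmer":
        raise ValueError(f"unknown similarity method {method!r}")
    if len(query) < k or len(target) < k:
        # too short for k-mers: fall back to exact identity comparison
        return 100.0 if query == target else 0.0
    qk = _kmers(query, k)
    return 100.0 * len(qk & _kmers(target, k)) / len(qk)


def filter_by_similarity(
    candidates: Sequence[ScoredSequence],
    holdout: Sequence[str],
    threshold: float = 40.0,
    method: str = "kmer",
) -> List[ScoredSequence]:
    """Drop candidates similar to any held-out sequence.

    A candidate is removed when its similarity to *any* holdout sequence is
    ``>= threshold`` percent (40 by default), preventing leakage from
    training data into evaluation splits.
    """
    if not holdout:
        raise ValueError("holdout must be non-empty")
    if not (0.0 < threshold <= 100.0):
        raise ValueError("threshold must lie in (0, 100]")
    kept = []
    for cand in candidates:
        if all(sequence_similarity(cand.sequence, h, method=method) < threshold
               for h in holdout):
            kept.append(cand)
    return kept


# ---------------------------------------------------------------------------
# cropping / augmentation / balancing

def crop_sequence(record: ScoredSequence, max_len: int = 500,
                  rng: Optional[np.random.Generator] = None) -> ScoredSequence:
    """Randomly crop a record to at most ``max_len`` residues.

    Sequences no longer than ``max_len`` are returned unchanged; otherwise a
    contiguous window of exactly ``max_len`` is chosen uniformly, and any
    per-residue scores are cropped with the same window.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    if len(record.sequence) <= max_len:
        return record
    rng = np.random.default_rng() if rng is None else rng
    start = int(rng.integers(0, len(record.sequence) - max_len + 1))
    scores = record.residue_scores
    return dataclasses.replace(
        record,
        sequence=record.sequence[start:start + max_len],
        residue_scores=None if scores is None else scores[start:start + max_len],
    )


def augment_perturb(
    record: ScoredSequence,
    rng: np.random.Generator,
    op: str = "segment_permute",
    intensity: float = 0.25,
    aa_freqs: Optional[np.ndarray] = None,
) -> UnscoredSequence:
    """Perturb a sequence to create an augmentation candidate (score unset).

    ``segment_permute`` shuffles a contiguous segment covering about
    ``intensity`` of the length; ``segment_replace`` substitutes such a
    segment with residues drawn from ``aa_freqs`` (uniform over the 20
    amino acids by default).  The perturbed sequence carries no score: it
    must be scored by an external scorer (a trained distill model or the
    synthetic oracle) before entering a training set, mirroring how
    augmented sequences are re-scored by the folding model.
    """
    if not (0.0 < intensity <= 1.0):
        raise ValueError("intensity must lie in (0, 1]")
    if op not in ("segment_permute", "segment_replace"):
        raise ValueError(f"unknown perturbation op {op!r}")
    seq = record.sequence
    L = len(seq)
    if L == 1:
        warnings.warn("length-1 sequence cannot be segment-perturbed; returned unchanged")
        return UnscoredSequence(id=f"{record.id}|aug", sequence=seq)
    seg_len = min(L, max(1, math.ceil(intensity * L)))
    start = int(rng.integers(0, L - seg_len + 1))
    chars = list(seq)
    if op == "segment_permute":
        segment = chars[start:start + seg_len]
        chars[start:start + seg_len] = [segment[i] for i in rng.permutation(seg_len)]
    else:
        if aa_freqs is None:
            aa_freqs = np.full(len(AA_ALPHABET), 1.0 / len(AA_ALPHABET))
        aa_freqs = np.asarray(aa_freqs, float)
        aa_freqs = aa_freqs / aa_freqs.sum()
        drawn = rng.choice(len(AA_ALPHABET), size=seg_len, p=aa_freqs)
        chars[start:start + seg_len] = [AA_ALPHABET[i] for i in drawn]
    return UnscoredSequence(id=f"{record.id}|aug", sequence="".join(chars))


def balance_filter(
    records: Sequence[ScoredSequence],
    keep_below: float,
    keep_fraction_above: float,
    rng: Optional[np.random.Generator] = None,
    binning: ScoreBinning = ScoreBinning(),
) -> Tuple[List[ScoredSequence], dict]:
    """Thin the over-represented upper score range.

    Records with mean score below ``keep_below`` are all kept; records at or
    above it are kept independently with probability
    ``keep_fraction_above``.  Returns the filtered list and a report with
    before/after bin histograms.
    """
    if not (0.0 < keep_below < 1.0):
        raise ValueError("keep_below cutoff must lie in (0, 1)")
    if not (0.0 <= keep_fraction_above <= 1.0):
        raise ValueError("keep_fraction_above must lie in [0, 1]")
    rng = np.random.default_rng() if rng is None else rng
    before = DatasetManifest(list(records), binning).bin_histogram()
    kept = [
        rec for rec in records
        if rec.mean_score() < keep_below or rng.random() < keep_fraction_above
    ]
    after = DatasetManifest(kept, binning).bin_histogram()
    report = {
        "n_before": len(records),
        "n_after": len(kept),
        "hist_before": before.tolist(),
        "hist_after": after.tolist(),
    }
    return kept, report


def sampling_weights(records: Sequence[ScoredSequence],
                     binning: ScoreBinning = ScoreBinning()) -> np.ndarray:
    """Inverse-bin-frequency minibatch sampling weights, normalized to sum 1.

    Each record's weight is proportional to ``1 / count(bin of its mean
    score)``, so expected bin exposure under weighted sampling is uniform
    over the occupied bins.
    """
    if not records:
        raise ValueError("records must be non-empty")
    labels = np.array([discretize_score(r.mean_score(), binning) for r in records])
    counts = np.bincount(labels, minlength=binning.n_bins)
    w = 1.0 / counts[labels]
    return w / w.sum()


def generate_synthetic_scored(
    n: int,
    scorer: Callable[[str], float],
    length_range: Tuple[int, int] = (30, 80),
    rng: Optional[np.random.Generator] = None,
    id_prefix: str = "syn",
    per_residue: bool = False,
) -> List[ScoredSequence]:
    """Random sequences over the 20-letter alphabet, scored by ``scorer``.

    ``scorer`` maps a sequence to a scalar in (0, 1); with
    ``per_residue=True`` it must return a per-residue array instead.  Used
    to populate the low-score range that curated structure-derived sets
    lack.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = length_range
    if not (1 <= lo <= hi):
        raise ValueError("invalid length_range")
    rng = np.random.default_rng() if rng is None else rng
    out = []
    for i in range(n):
        L = int(rng.integers(lo, hi + 1))
        seq = "".join(AA_ALPHABET[j] for j in rng.integers(0, len(AA_ALPHABET), size=L))
        score = scorer(seq)
        arr = np.asarray(score, float)
        if per_residue and arr.ndim != 1:
            raise ValueError("per_residue=True requires a scorer returning a "
                             "per-residue array (e.g. an oracle's score_track)")
        if np.any(~np.isfinite(arr)) or np.any(arr <= 0) or np.any(arr >= 1):
            raise ValueError("scorer returned value(s) outside (0, 1)")
        rec = ScoredSequence(
            id=f"{id_prefix}-{i:05d}",
            sequence=seq,
            scalar_score=None if per_residue else float(arr),
            residue_scores=arr if per_residue else None,
            provenance="synthetic",
        )
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# IO

def plddt_to_unit(x) -> np.ndarray:
    """Convert pLDDT on the 0-100 reporting scale to the internal (0, 1) scale."""
    return np.asarray(x, float) / 100.0


def plddt_from_unit(x) -> np.ndarray:
    """Convert internal (0, 1) scores back to the 0-100 pLDDT reporting scale."""
    return np.asarray(x, float) * 100.0


def write_jsonl(records: Sequence[ScoredSequence], path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            obj = {
                "id": rec.id,
                "sequence": rec.sequence,
                "scalar_score": rec.scalar_score,
                "residue_scores": (
                    None if rec.residue_scores is None
                    else [round(float(v), 6) for v in rec.residue_scores]
                ),
                "provenance": rec.provenance,
            }
            fh.write(json.dumps(obj) + "\n")


def read_jsonl(path) -> List[ScoredSequence]:
    out = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            if not line.strip():
                continue
            obj = json.loads(line)
            try:
                out.append(ScoredSequence(
                    id=obj["id"],
                    sequence=obj["sequence"],
                    scalar_score=obj.get("scalar_score"),
                    residue_scores=obj.get("residue_scores"),
                    provenance=obj.get("provenance", "original"),
                ))
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}:{line_no}: invalid record: {exc}") from exc
    return out


def write_csv(records: Sequence[ScoredSequence], path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "sequence", "scalar_score", "mean_residue_score",
                         "provenance"])
        for rec in records:
            writer.writerow([
                rec.id, rec.sequence,
                "" if rec.scalar_score is None else f"{rec.scalar_score:.6f}",
                "" if rec.residue_scores is None else f"{rec.residue_scores.mean():.6f}",
                rec.provenance,
            ])


def read_fasta(path) -> List[Tuple[str, str]]:
    """Read (id, sequence) pairs from a FASTA file."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(entries: Sequence[Tuple[str, str]], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in entries]
    SeqIO.write(records, str(path), "fasta")
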