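"""Structure-similarity metrics: TM-score, LDDT and neighbor-density classes.

TM-score is a length-normalized similarity in (0, 1] that averages
``1 / (1 + (d_i / d0)^2)`` over aligned C-alpha pairs under the best rigid
superposition, with the length-dependent scale
``d0 = 1.24 (L_ref - 15)^(1/3) - 1.8`` (clamped below at 0.5 A for short
chains).  LDDT is superposition-free: it scores how well reference
inter-residue distances inside a 15 A inclusion radius are preserved, at
the four tolerances {0.5, 1, 2, 4} A, averaged per residue.

The TM superposition search is a deterministic iterative refinement:
Kabsch fits seeded from the full correspondence and its two halves, each
refined by repeatedly re-fitting on the pairs within distance cutoffs
{8, 6, 4} A until the inlier set is stable; the maximum TM over all visited
superpositions is returned.  This keeps the score reproducible while
closely tracking the metric's defining iterative search.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.spatial.distance import cdist

from .structure import BackboneStructure, Superposition, kabsch_superpose

__all__ = [
    "StructureScore",
    "tm_d0",
    "tm_score",
    "lddt",
    "lddt_from_distance_matrices",
    "neighbor_density_class",
    "NeighborClass",
    "LDDT_TOLERANCES",
    "LDDT_INCLUSION_RADIUS",
]

logger = logging.getLogger(__name__)

#: LDDT tolerance thresholds in Angstrom (the metric's standard four).
LDDT_TOLERANCES: Tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)
#: Reference-distance inclusion radius in Angstrom.
LDDT_INCLUSION_RADIUS: float = 15.0

#: Core/surface neighbor-count thresholds (C-alpha within 10 A).
NEIGHBOR_RADIUS: float = 10.0
CORE_MIN_NEIGHBORS: int = 24
SURFACE_MAX_NEIGHBORS: int = 16

_D0_CLAMP = 0.5
_TM_REFINE_CUTOFFS: Tuple[float, ...] = (8.0, 6.0, 4.0)


@dataclasses.dataclass(frozen=True)
class StructureScore:
    """TM plus global/per-residue LDDT for a model/reference pair.

    ``lddt_per_residue`` may contain NaN for residues with no reference
    pair inside the inclusion radius; those are excluded from the global
    mean, which otherwise equals the per-residue mean exactly.
    """

    tm: float
    lddt_global: float
    lddt_per_residue: np.ndarray

    def __post_init__(self) -> None:
        if not (0.0 < self.tm <= 1.0 + 1e-12):
            raise ValueError(f"tm must be in (0, 1], got {self.tm}")
        finite = self.lddt_per_residue[np.isfinite(self.lddt_per_residue)]
        if finite.size and not np.allclose(self.lddt_global, finite.mean()):
            raise ValueError("lddt_global must equal the mean of per-residue values")
        if np.any((finite < -1e-12) | (finite > 1 + 1e-12)):
            raise ValueError("per-residue LDDT values must lie in [0, 1]")


def tm_d0(l_ref: int) -> float:
    """Length-dependent TM distance scale, clamped below at 0.5 A.

    The cube-root formula turns non-positive for ``l_ref <= 21``; the clamp
    keeps the score well-defined on toy-sized chains.
    """
    if l_ref < 1:
        raise ValueError("reference length must be positive")
    return max(1.24 * np.cbrt(max(l_ref - 15, 0)) - 1.8, _D0_CLAMP)


def _tm_from_distances(d: np.ndarray, d0: float, l_ref: int) -> float:
    return float(np.sum(1.0 / (1.0 + (d / d0) ** 2)) / l_ref)


def _refine(mov: np.ndarray, fix: np.ndarray, seed_idx: np.ndarray,
            d0: float, l_ref: int):
    """Refinement from one Kabsch seed; yields (tm, superposition) candidates."""
    out = []
    try:
        sup = kabsch_superpose(mov[seed_idx], fix[seed_idx])
    except ValueError:
        return out
    d = np.linalg.norm(sup.apply(mov) - fix, axis=1)
    out.append((_tm_from_distances(d, d0, l_ref), sup))
    for cutoff in _TM_REFINE_CUTOFFS:
        prev = None
        for _ in range(20):
            inliers = np.flatnonzero(d < cutoff)
            if inliers.size < 3:
                break
            if prev is not None and inliers.size == prev.size and np.all(inliers == prev):
                break
            prev = inliers
            sup = kabsch_superpose(mov[inliers], fix[inliers])
            d = np.linalg.norm(sup.apply(mov) - fix, axis=1)
            out.append((_tm_from_distances(d, d0, l_ref), sup))
    return out


def tm_score(
    model: BackboneStructure,
    reference: BackboneStructure,
    correspondence: Optional[Sequence[Tuple[int, int]]] = None,
    return_superposition: bool = False,
):
    """TM-score of ``model`` against ``reference`` over aligned C-alpha pairs.

    ``correspondence`` lists ``(model_index, reference_index)`` pairs
    (0-based); by default it is positional, requiring equal lengths.  The
    normalization length is the reference length.

    Returns the score, or ``(score, Superposition)`` when
    ``return_superposition`` is set.
    """
    if correspondence is None:
        if len(model) != len(reference):
            raise ValueError(
                "positional correspondence requires equal lengths "
                f"({len(model)} vs {len(reference)})"
            )
        pairs = np.column_stack([np.arange(len(model))] * 2)
    else:
        pairs = np.asarray(list(correspondence), dtype=int)
        if pairs.size == 0:
            raise ValueError("correspondence must be non-empty")
        if pairs.ndim != 2 or pairs.shape[1] != 2:
            raise ValueError("correspondence must be (model_idx, reference_idx) pairs")
        if pairs[:, 0].max() >= len(model) or pairs[:, 1].max() >= len(reference) \
                or pairs.min() < 0:
            raise ValueError("correspondence indices out of range")
    mov = model.ca_coords[pairs[:, 0]]
    fix = reference.ca_coords[pairs[:, 1]]
    l_ref = len(reference)
    d0 = tm_d0(l_ref)
    n = len(pairs)
    seeds = [np.arange(n)]
    if n >= 6:
        seeds.append(np.arange(n // 2))
        seeds.append(np.arange(n // 2, n))
    best_tm, best_sup = -1.0, None
    for seed in seeds:
        for tm, sup in _refine(mov, fix, seed, d0, l_ref):
            if tm > best_tm:
                best_tm, best_sup = tm, sup
    if best_sup is None:
        raise ValueError("superposition failed (fewer than 3 usable pairs)")
    return (best_tm, best_sup) if return_superposition else best_tm


def lddt_from_distance_matrices(
    d_model: np.ndarray,
    d_reference: np.ndarray,
    inclusion_radius: float = LDDT_INCLUSION_RADIUS,
    tolerances: Sequence[float] = LDDT_TOLERANCES,
) -> Tuple[float, np.ndarray]:
    """LDDT from precomputed symmetric distance matrices.

    A reference pair (i, j), i != j, is included when its reference distance
    is strictly below ``inclusion_radius``; it is preserved at tolerance t
    when ``|d_model - d_reference| < t``.  Per-residue score: mean over
    tolerances of the preserved fraction of that residue's included pairs;
    residues with no included pair get NaN and are excluded from the global
    mean.

    Returns ``(global_lddt, per_residue)``.
    """
    d_model = np.asarray(d_model, float)
    d_ref = np.asarray(d_reference, float)
    if d_model.shape != d_ref.shape or d_model.ndim != 2 \
            or d_model.shape[0] != d_model.shape[1]:
        raise ValueError("distance matrices must be square and of equal shape")
    n = d_ref.shape[0]
    if n < 2:
        raise ValueError("LDDT requires at least 2 residues")
    include = (d_ref < inclusion_radius) & ~np.eye(n, dtype=bool)
    delta = np.abs(d_model - d_ref)
    per_res = np.full(n, np.nan)
    counts = include.sum(axis=1)
    for t_i, tol in enumerate(tolerances):
        preserved = (delta < tol) & include
        frac = np.divide(
            preserved.sum(axis=1), counts,
            out=np.zeros(n), where=counts > 0,
        )
        per_res = np.where(counts > 0, (0.0 if t_i == 0 else per_res) + frac, np.nan)
    per_res = per_res / len(tolerances)
    if np.any(counts == 0):
        logger.warning(
            "%d residue(s) have no reference pair within %.1f A; "
            "excluded from global LDDT", int((counts == 0).sum()), inclusion_radius,
        )
    finite = per_res[np.isfinite(per_res)]
    if finite.size == 0:
        raise ValueError("no residue has any pair inside the inclusion radius")
    return float(finite.mean()), per_res


def _atom_coords(structure: BackboneStructure, all_atom: bool) -> Tuple[np.ndarray, np.ndarray]:
    """Flat (n_atoms, 3) coordinates plus the residue index of each atom."""
    if all_atom:
        if structure.atom_records is None:
            raise ValueError("all-atom LDDT requested but atom_records are absent")
        coords, owner = [], []
        for i, res in enumerate(structure.atom_records):
            for _, xyz in res:
                coords.append(xyz)
                owner.append(i)
        return np.asarray(coords, float), np.asarray(owner, int)
    return structure.ca_coords, np.arange(len(structure))


def lddt(
    model: BackboneStructure,
    reference: BackboneStructure,
    all_atom: bool = False,
    inclusion_radius: float = LDDT_INCLUSION_RADIUS,
    tolerances: Sequence[float] = LDDT_TOLERANCES,
) -> Tuple[float, np.ndarray]:
    """Superposition-free LDDT of ``model`` against ``reference``.

    Correspondence is positional (equal residue counts).  Default mode uses
    C-alpha atoms only; ``all_atom=True`` uses every atom in
    ``atom_records`` (pairs from different residues only), aggregating
    per-residue over the atoms each residue owns.

    Returns ``(global_lddt, per_residue)``.
    """
    if len(model) != len(reference):
        raise ValueError("LDDT requires equal residue counts (positional correspondence)")
    if len(reference) < 2:
        raise ValueError("LDDT requires at least 2 residues")
    if not all_atom:
        dm = cdist(model.ca_coords, model.ca_coords)
        dr = cdist(reference.ca_coords, reference.ca_coords)
        return lddt_from_distance_matrices(dm, dr, inclusion_radius, tolerances)

    ref_xyz, owner = _atom_coords(reference, True)
    mod_xyz, owner_m = _atom_coords(model, True)
    if len(ref_xyz) != len(mod_xyz) or np.any(owner != owner_m):
        raise ValueError("all-atom LDDT requires matching atom records")
    dr = cdist(ref_xyz, ref_xyz)
    dm = cdist(mod_xyz, mod_xyz)
    include = (dr < inclusion_radius) & (owner[:, None] != owner[None, :])
    delta = np.abs(dm - dr)
    n = len(reference)
    per_res = np.full(n, np.nan)
    for i in range(n):
        rows = owner == i
        inc = include[rows]
        total = inc.sum()
        if total == 0:
            continue
        fracs = [float(((delta[rows] < t) & inc).sum()) / total for t in tolerances]
        per_res[i] = float(np.mean(fracs))
    finite = per_res[np.isfinite(per_res)]
    if finite.size == 0:
        raise ValueError("no residue has any pair inside the inclusion radius")
    if np.any(~np.isfinite(per_res)):
        logger.warning(
            "%d residue(s) excluded from global all-atom LDDT",
            int(np.sum(~np.isfinite(per_res))),
        )
    return float(finite.mean()), per_res


def structure_score(model: BackboneStructure, reference: BackboneStructure) -> StructureScore:
    """Convenience bundle: TM plus LDDT (C-alpha) for a model/reference pair."""
    g, per = lddt(model, reference)
    return StructureScore(tm=tm_score(model, reference), lddt_global=g, lddt_per_residue=per)


@dataclasses.dataclass(frozen=True)
class NeighborClass:
    label: str  # "core" | "surface" | "intermediate"
    n_neighbors: int


def neighbor_density_class(
    structure: BackboneStructure,
    index: int,
    radius: float = NEIGHBOR_RADIUS,
    core_min: int = CORE_MIN_NEIGHBORS,
    surface_max: int = SURFACE_MAX_NEIGHBORS,
) -> NeighborClass:
    """Classify residue ``index`` by C-alpha neighbor density.

    Counts other residues' C-alpha atoms within ``radius`` (10 A default);
    >= 24 neighbors is core, <= 16 is surface, anything between is
    intermediate.
    """
    n = len(structure)
    if not (0 <= index < n):
        raise IndexError(f"residue index {index} out of range [0, {n})")
    d = np.linalg.norm(structure.ca_coords - structure.ca_coords[index], axis=1)
    count = int(np.sum(d <= radius)) - 1  # exclude self
    if count >= core_min:
        label = "core"
    elif count <= surface_max:
        label = "surface"
    else:
        label = "intermediate"
    return NeighborClass(label=label, n_neighbors=count)


def neighbor_classes(structure: BackboneStructure, **kwargs) -> list:
    """Neighbor-density class labels for every residue."""
    return [neighbor_density_class(structure, i, **kwargs).label
            for i in range(len(structure))]
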