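"""Minimal-RMSD superposition, neighbor lists and ensemble deduplication.

The superposition is the classic Kabsch construction: both point sets are
centered, the optimal *proper* rotation is obtained from the SVD of the
covariance matrix with a determinant correction, and the RMSD is evaluated
after applying it.  Reflections are excluded on purpose — mirroring a
chiral conformer onto its enantiomer must not report RMSD 0.

Atom correspondence is by index (conformers from dynamics preserve atom
order); no permutation search is performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .structures import AtomicStructure, ConformerEnsemble

__all__ = [
    "NeighborList",
    "kabsch_rotation",
    "kabsch_rmsd",
    "build_neighbor_list",
    "deduplicate",
]


@dataclass
class NeighborList:
    """Directed pair list (i, j, d_ij) for all pairs with d_ij <= cutoff."""

    i: np.ndarray  # center atom indices
    j: np.ndarray  # neighbor atom indices
    d: np.ndarray  # distances, angstrom
    cutoff: float

    @property
    def pairs(self) -> list[tuple[int, int, float]]:
        return [(int(a), int(b), float(x)) for a, b, x in zip(self.i, self.j, self.d)]


def _check_compatible(a: AtomicStructure, b: AtomicStructure) -> None:
    if not np.array_equal(a.elements, b.elements):
        raise ValueError("structures differ in element sequence; cannot superpose")


def kabsch_rotation(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal proper rotation R minimizing ||p_c - q_c R^T||.

    Returns ``(R, p_centered, q_centered)`` where ``R @ q_centered[i]``
    best matches ``p_centered[i]``.
    """
    p_c = p - p.mean(axis=0)
    q_c = q - q.mean(axis=0)
    h = q_c.T @ p_c  # 3x3 covariance
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    r = vt.T @ corr @ u.T
    return r, p_c, q_c


def kabsch_rmsd(a: AtomicStructure, b: AtomicStructure) -> float:
    """Minimal RMSD between index-matched structures over rigid motions."""
    _check_compatible(a, b)
    r, p_c, q_c = kabsch_rotation(a.coords, b.coords)
    diff = p_c - q_c @ r.T
    return float(np.sqrt((diff**2).sum() / len(p_c)))


def build_neighbor_list(s: AtomicStructure, cutoff: float) -> NeighborList:
    """All directed pairs with Euclidean distance <= cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    n = s.n_atoms
    if n < 2:
        return NeighborList(
            np.empty(0, np.intp), np.empty(0, np.intp), np.empty(0), cutoff
        )
    dmat = squareform(pdist(s.coords))
    ii, jj = np.nonzero((dmat <= cutoff) & ~np.eye(n, dtype=bool))
    return NeighborList(ii, jj, dmat[ii, jj], cutoff)


def deduplicate(e: ConformerEnsemble, cutoff: float = 0.1) -> ConformerEnsemble:
    """Remove near-duplicate conformers by a greedy keep-first RMSD scan.

    A member is kept iff its minimal RMSD to every already-kept member
    exceeds ``cutoff`` (default 0.1 angstrom); kept members preserve input
    order.  Greedy keep-first is deterministic; note the final kept set is
    only guaranteed separated from each survivor at its insertion time.
    """
    kept: list[AtomicStructure] = []
    for m in e.members:
        if all(kabsch_rmsd(m, k) > cutoff for k in kept):
            kept.append(m)
    return ConformerEnsemble(e.configuration_id, kept)
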