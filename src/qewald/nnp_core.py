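"""Short-range message-passing potential (continuous-filter convolutions).

The baseline model follows the SchNet family: atomic numbers are embedded
into F-dimensional feature vectors, T interaction blocks exchange messages
between atoms within a distance cutoff using filters generated from a
Gaussian radial expansion of the pair distance, and an atom-wise readout
maps final embeddings to atomic energies that sum to the total energy.

Message passing for block t:

    m_i = sum_{j in N(i)}  W_filter(e_ij) * (x_j W_a + b_a)
    h_i' = h_i + U(m_i)

with e_ij the radial features of d_ij.  The filter net's final layer and
the update net U carry no bias and use the shifted softplus (ssp(0) = 0),
so an atom with an empty neighborhood is exactly unchanged.

Everything is built on the package's autodiff tensors, so the same
forward code yields parameter gradients for training and coordinate
gradients for diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .autodiff import Tensor, as_tensor, segment_sum
from .geometry import NeighborList, build_neighbor_list
from .structures import AtomicStructure

__all__ = [
    "AtomEmbeddings",
    "RadialBasis",
    "InteractionParams",
    "ReadoutParams",
    "BaselineParams",
    "StructureBatch",
    "embed",
    "radial_expansion",
    "interaction_step",
    "readout_energy",
    "baseline_forward",
]

MAX_Z = 54  # covers H..Xe, matching the symbol table in structures


@dataclass
class AtomEmbeddings:
    """Per-atom feature matrix x (N, F); row order matches atom order."""

    x: Tensor

    @property
    def n_features(self) -> int:
        return self.x.shape[1]


@dataclass
class RadialBasis:
    """Gaussian radial expansion with a smooth cosine cutoff envelope."""

    n_rbf: int = 32
    cutoff: float = 5.0
    width: float | None = None  # 1/A^2; default set from center spacing

    def __post_init__(self):
        self.centers = np.linspace(0.0, self.cutoff, self.n_rbf)
        if self.width is None:
            spacing = self.cutoff / max(self.n_rbf - 1, 1)
            self.width = 0.5 / spacing**2


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int) -> Tensor:
    scale = np.sqrt(2.0 / (fan_in + fan_out))
    return Tensor(rng.normal(0.0, scale, size=(fan_in, fan_out)), requires_grad=True)


def _zeros(*shape: int) -> Tensor:
    return Tensor(np.zeros(shape), requires_grad=True)


@dataclass
class InteractionParams:
    """Weights of one continuous-filter interaction block."""

    w_filter1: Tensor  # (K, F)
    b_filter1: Tensor  # (F,)
    w_filter2: Tensor  # (F, F), no bias: empty neighborhood -> zero message
    w_atom: Tensor  # (F, F)
    b_atom: Tensor  # (F,)
    w_update1: Tensor  # (F, F), bias-free so U(0) = 0 exactly
    w_update2: Tensor  # (F, F)

    @classmethod
    def init(cls, rng: np.random.Generator, n_features: int, n_rbf: int):
        return cls(
            w_filter1=_xavier(rng, n_rbf, n_features),
            b_filter1=_zeros(n_features),
            w_filter2=_xavier(rng, n_features, n_features),
            w_atom=_xavier(rng, n_features, n_features),
            b_atom=_zeros(n_features),
            w_update1=_xavier(rng, n_features, n_features),
            w_update2=_xavier(rng, n_features, n_features),
        )

    def parameters(self):
        return [
            self.w_filter1,
            self.b_filter1,
            self.w_filter2,
            self.w_atom,
            self.b_atom,
            self.w_update1,
            self.w_update2,
        ]


@dataclass
class ReadoutParams:
    """Atom-wise energy head plus trainable per-element offsets (kcal/mol)."""

    w1: Tensor  # (F, F//2)
    b1: Tensor
    w2: Tensor  # (F//2, 1)
    b2: Tensor
    offsets: Tensor  # (MAX_Z+1, 1)

    @classmethod
    def init(cls, rng: np.random.Generator, n_features: int):
        h = max(n_features // 2, 1)
        return cls(
            w1=_xavier(rng, n_features, h),
            b1=_zeros(h),
            w2=_xavier(rng, h, 1),
            b2=_zeros(1),
            offsets=_zeros(MAX_Z + 1, 1),
        )

    def parameters(self):
        return [self.w1, self.b1, self.w2, self.b2, self.offsets]


@dataclass
class BaselineParams:
    """Everything trainable in the short-range model."""

    embedding: Tensor  # (MAX_Z+1, F) lookup table
    rbf: RadialBasis
    blocks: list[InteractionParams]
    readout: ReadoutParams

    @classmethod
    def init(
        cls,
        rng: np.random.Generator,
        n_features: int = 64,
        n_blocks: int = 3,
        n_rbf: int = 32,
        cutoff: float = 5.0,
    ):
        return cls(
            embedding=Tensor(
                rng.normal(0.0, 1.0, size=(MAX_Z + 1, n_features)),
                requires_grad=True,
            ),
            rbf=RadialBasis(n_rbf=n_rbf, cutoff=cutoff),
            blocks=[
                InteractionParams.init(rng, n_features, n_rbf)
                for _ in range(n_blocks)
            ],
            readout=ReadoutParams.init(rng, n_features),
        )

    @property
    def n_features(self) -> int:
        return self.embedding.shape[1]

    def parameters(self) -> list[Tensor]:
        ps = [self.embedding]
        for b in self.blocks:
            ps.extend(b.parameters())
        ps.extend(self.readout.parameters())
        return ps


# ---------------------------------------------------------------------------
# batching
# ---------------------------------------------------------------------------


@dataclass
class StructureBatch:
    """Several structures concatenated along the atom axis.

    ``seg`` maps each atom to its structure; neighbor pairs are built per
    structure and offset into the concatenated index space, so messages
    never cross structure boundaries.
    """

    elements: np.ndarray  # (n_atoms,)
    coords: Tensor  # (n_atoms, 3) graph leaf
    seg: np.ndarray  # (n_atoms,) structure index per atom
    pair_i: np.ndarray
    pair_j: np.ndarray
    n_structures: int
    total_charges: np.ndarray  # (n_structures,)
    n_atoms_per: np.ndarray  # (n_structures,)

    @classmethod
    def from_structures(
        cls, structures: Sequence[AtomicStructure], cutoff: float
    ) -> "StructureBatch":
        elements, coords, seg, pi, pj, qs, nper = [], [], [], [], [], [], []
        offset = 0
        for k, s in enumerate(structures):
            elements.append(s.elements)
            coords.append(s.coords)
            seg.append(np.full(s.n_atoms, k))
            nl = build_neighbor_list(s, cutoff)
            pi.append(nl.i + offset)
            pj.append(nl.j + offset)
            qs.append(s.total_charge)
            nper.append(s.n_atoms)
            offset += s.n_atoms
        return cls(
            elements=np.concatenate(elements),
            coords=Tensor(np.concatenate(coords, axis=0), requires_grad=True),
            seg=np.concatenate(seg),
            pair_i=np.concatenate(pi).astype(np.intp),
            pair_j=np.concatenate(pj).astype(np.intp),
            n_structures=len(structures),
            total_charges=np.array(qs, dtype=np.float64),
            n_atoms_per=np.array(nper, dtype=np.intp),
        )

    def pair_distances(self) -> Tensor:
        """Differentiable pair distances gathered from the coordinates."""
        ri = self.coords.gather(self.pair_i)
        rj = self.coords.gather(self.pair_j)
        diff = ri - rj
        return (diff * diff).sum(axis=1).sqrt()


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def embed(elements: Sequence[int], table) -> AtomEmbeddings:
    """Look up per-element feature vectors.

    ``table`` is either a dict {Z: vector} or an array/Tensor indexed by Z
    (gradients flow through Tensor tables).
    """
    z = np.asarray(elements, dtype=np.intp)
    if isinstance(table, dict):
        missing = [int(zz) for zz in z if int(zz) not in table]
        if missing:
            raise KeyError(f"no embedding for element Z={missing[0]}")
        return AtomEmbeddings(Tensor(np.stack([np.asarray(table[int(zz)]) for zz in z])))
    table = as_tensor(table)
    if np.any(z >= table.shape[0]):
        raise KeyError(f"no embedding for element Z={int(z.max())}")
    return AtomEmbeddings(table.gather(z))


def radial_expansion(d, basis: RadialBasis) -> Tensor:
    """Gaussian expansion of distances with the cutoff envelope applied.

    Accepts a scalar, array or Tensor of distances; returns (P, K).
    """
    d = as_tensor(d)
    flat = d.reshape(-1, 1)
    centers = Tensor(basis.centers.reshape(1, -1))
    gauss = (-(basis.width) * (flat - centers) ** 2.0).exp()
    # cosine envelope, exactly zero at and beyond the cutoff
    inside = (d.data.reshape(-1, 1) < basis.cutoff).astype(np.float64)
    env = ((flat * (np.pi / basis.cutoff)).cos() + 1.0) * 0.5 * Tensor(inside)
    return gauss * env


def interaction_step(
    x: AtomEmbeddings,
    nl,
    rb: RadialBasis,
    w: InteractionParams,
    d: Tensor | None = None,
) -> AtomEmbeddings:
    """One continuous-filter message-passing block with residual update.

    ``nl`` supplies pair indices (a NeighborList or a StructureBatch);
    ``d`` optionally provides differentiable pair distances, otherwise the
    neighbor-list distances are used as constants.
    """
    if isinstance(nl, StructureBatch):
        pi, pj = nl.pair_i, nl.pair_j
        if d is None:
            d = nl.pair_distances()
    else:
        pi, pj = np.asarray(nl.i, np.intp), np.asarray(nl.j, np.intp)
        if d is None:
            d = Tensor(np.asarray(nl.d))
    h = x.x
    n = h.shape[0]
    e = radial_expansion(d, rb)  # (P, K)
    filt = ((e @ w.w_filter1) + w.b_filter1).ssp() @ w.w_filter2  # (P, F)
    a = (h @ w.w_atom) + w.b_atom
    contrib = filt * a.gather(pj)
    m = segment_sum(contrib, pi, n)  # zero rows for empty neighborhoods
    u = (m @ w.w_update1).ssp() @ w.w_update2  # U(0) = 0 exactly
    return AtomEmbeddings(h + u)


def readout_energy(
    x: AtomEmbeddings,
    elements: Sequence[int],
    r: ReadoutParams,
    seg: np.ndarray | None = None,
    n_structures: int = 1,
) -> tuple[Tensor, Tensor]:
    """Atom-wise energies and their (per-structure) sum in kcal/mol."""
    z = np.asarray(elements, dtype=np.intp)
    per_atom = ((x.x @ r.w1) + r.b1).ssp() @ r.w2 + r.b2  # (N, 1)
    per_atom = per_atom + r.offsets.gather(z)
    if seg is None:
        seg = np.zeros(len(z), dtype=np.intp)
    totals = segment_sum(per_atom, seg, n_structures).reshape(n_structures)
    return per_atom.reshape(-1), totals


def baseline_atomic_embeddings(batch: StructureBatch, params: BaselineParams) -> AtomEmbeddings:
    """Embed and run all interaction blocks on a batch."""
    x = embed(batch.elements, params.embedding)
    d = batch.pair_distances()
    for blk in params.blocks:
        x = interaction_step(x, batch, params.rbf, blk, d=d)
    return x


def baseline_energies(batch: StructureBatch, params: BaselineParams) -> Tensor:
    """Total energies (n_structures,) of a batch under the baseline model."""
    x = baseline_atomic_embeddings(batch, params)
    _, totals = readout_energy(
        x, batch.elements, params.readout, seg=batch.seg, n_structures=batch.n_structures
    )
    return totals


def baseline_forward(s: AtomicStructure, params: BaselineParams) -> float:
    """Baseline total energy of a single structure, kcal/mol."""
    batch = StructureBatch.from_structures([s], params.rbf.cutoff)
    return float(baseline_energies(batch, params).data[0])
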