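"""Synthetic conformer generation: toy potential + RMSD-biased metadynamics.

This module is the data-generating stand-in for an ab initio labeling
pipeline.  The ground-truth energy of a cluster is an explicit sum of a
short-range pairwise part (Morse terms, optionally plus Gaussian bumps for
building multi-well toys) and a long-range Coulomb part over fixed
ground-truth partial charges:

    E(r) = sum_{i<j, d<=cutoff} V_sr(d_ij)  +  k_C sum_{i<j} q_i q_j / d_ij

with k_C = 332.0637 kcal*A/(mol*e^2).  The 1/r tail extends beyond any
local message-passing cutoff, which is what makes a long-range model
branch worth having.

Conformers are sampled by Langevin dynamics (BAOAB splitting) on the
ground-truth surface plus a history-dependent bias

    V_bias(r) = sum_i k_i exp(-alpha_i * Delta_i^2)

where Delta_i is the minimal (Kabsch-aligned) RMSD to the i-th previously
deposited reference structure, k_i the pushing strength (kcal/mol) and
alpha_i the width (1/A^2).  The bias force uses the exact gradient of the
aligned RMSD: with both structures centered and R the optimal rotation,
d(Delta^2)/dr = (2/N) (r_c - R ref_c); the rotation's own dependence on r
drops out by stationarity of the Kabsch optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .structures import AtomicStructure, ConformerEnsemble

__all__ = [
    "COULOMB_CONSTANT",
    "KB_KCAL",
    "ToyPotentialParams",
    "MetaBiasParams",
    "toy_energy",
    "toy_forces",
    "bias_energy",
    "bias_forces",
    "metamd_sample",
    "generate_dataset",
    "default_toy_params",
    "make_cluster",
    "double_well_system",
]

COULOMB_CONSTANT = 332.0637  # kcal*A/(mol*e^2)
KB_KCAL = 0.0019872041  # kcal/(mol*K)
# 1 amu*A^2/fs^2 = 2390.057 kcal/mol: divides forces into accelerations
_KCAL_PER_AMU_A2_FS2 = 2390.057

_MASSES = {1: 1.008, 6: 12.011, 7: 14.007, 8: 15.999, 16: 32.06, 30: 65.38}


@dataclass
class ToyPotentialParams:
    """Ground-truth potential parameters.

    ``pair_terms`` maps an unordered element pair (z_min, z_max) to a list
    of short-range terms, each either ``("morse", depth, width, r_eq)``
    (well depth kcal/mol, width 1/A, equilibrium distance A; the Morse
    minimum value is -depth) or ``("gauss", height, alpha, center)``.

    ``charges`` optionally fixes per-atom ground-truth charges (e) for a
    specific composition; otherwise ``element_charges`` assigns a base
    charge per element and the residual Q - sum(base) is spread uniformly
    so the charges always sum to the structure's total charge.
    """

    pair_terms: dict[tuple[int, int], list[tuple]]
    charges: np.ndarray | None = None
    element_charges: dict[int, float] = field(default_factory=dict)
    coulomb_constant: float = COULOMB_CONSTANT
    sr_cutoff: float = 8.0

    def ground_truth_charges(self, s: AtomicStructure) -> np.ndarray:
        if self.charges is not None:
            q = np.asarray(self.charges, dtype=np.float64)
            if len(q) != s.n_atoms:
                raise ValueError("fixed charges length does not match structure")
        else:
            q = np.array(
                [self.element_charges.get(int(z), 0.0) for z in s.elements]
            )
        # uniform shift enforces sum(q) == Q exactly
        return q + (s.total_charge - q.sum()) / s.n_atoms


@dataclass
class MetaBiasParams:
    """Accumulated bias: reference structures with strengths and widths."""

    references: list[AtomicStructure] = field(default_factory=list)
    k: list[float] = field(default_factory=list)
    alpha: list[float] = field(default_factory=list)

    def __post_init__(self):
        if not (len(self.k) == len(self.alpha) == len(self.references)):
            raise ValueError("references, k and alpha must have equal length")
        if any(ki < 0 for ki in self.k):
            raise ValueError("pushing strengths must be nonnegative")
        if any(ai <= 0 for ai in self.alpha):
            raise ValueError("widths must be positive")

    def deposit(self, s: AtomicStructure, k: float, alpha: float) -> None:
        self.references.append(s.copy())
        self.k.append(float(k))
        self.alpha.append(float(alpha))


class _CompiledPairs:
    """Vectorized pair tables for one element sequence under one parameter set."""

    def __init__(self, elements: np.ndarray, p: "ToyPotentialParams",
                 q: np.ndarray):
        n = len(elements)
        ii, jj = np.triu_indices(n, k=1)
        self.i, self.j = ii, jj
        self.qq = p.coulomb_constant * q[ii] * q[jj]
        morse, gauss = [], []  # (pair_row, a, b, c) per term
        for row, (a, b) in enumerate(zip(ii, jj)):
            key = _pair_key(int(elements[a]), int(elements[b]))
            if key not in p.pair_terms:
                raise KeyError(f"element pair {key} not parameterized")
            for t in p.pair_terms[key]:
                if t[0] == "morse":
                    morse.append((row, t[1], t[2], t[3]))
                elif t[0] == "gauss":
                    gauss.append((row, t[1], t[2], t[3]))
                else:
                    raise ValueError(f"unknown short-range term kind {t[0]!r}")
        self.morse = np.array(morse, dtype=np.float64).reshape(-1, 4)
        self.gauss = np.array(gauss, dtype=np.float64).reshape(-1, 4)
        self.sr_cutoff = p.sr_cutoff

    def energy_forces(self, coords: np.ndarray, want_forces: bool):
        dv = coords[self.i] - coords[self.j]
        d = np.linalg.norm(dv, axis=1)
        if np.any(d < 1e-6):
            bad = int(np.argmin(d))
            raise ValueError(
                f"coincident atoms {self.i[bad]} and {self.j[bad]} "
                f"(d={d[bad]:g} A)"
            )
        e = np.sum(self.qq / d)
        de = -self.qq / d**2  # dE/dd per pair
        inside = d <= self.sr_cutoff
        if len(self.morse):
            rows = self.morse[:, 0].astype(np.intp)
            depth, width, req = self.morse[:, 1], self.morse[:, 2], self.morse[:, 3]
            dm = d[rows]
            ok = inside[rows]
            ex = np.exp(-width * (dm - req))
            e += np.sum((depth * (1.0 - ex) ** 2 - depth) * ok)
            if want_forces:
                np.add.at(de, rows, 2.0 * depth * width * ex * (1.0 - ex) * ok)
        if len(self.gauss):
            rows = self.gauss[:, 0].astype(np.intp)
            h, al, c0 = self.gauss[:, 1], self.gauss[:, 2], self.gauss[:, 3]
            dg = d[rows]
            ok = inside[rows]
            gval = h * np.exp(-al * (dg - c0) ** 2)
            e += np.sum(gval * ok)
            if want_forces:
                np.add.at(de, rows, -2.0 * al * (dg - c0) * gval * ok)
        if not want_forces:
            return float(e), None
        fpair = (-de / d)[:, None] * dv  # force on atom i of each pair
        f = np.zeros_like(coords)
        np.add.at(f, self.i, fpair)
        np.add.at(f, self.j, -fpair)
        return float(e), f


def _compiled(s: AtomicStructure, p: "ToyPotentialParams") -> _CompiledPairs:
    key = (s.elements.tobytes(), s.total_charge)
    cache = getattr(p, "_compiled_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(p, "_compiled_cache", cache)
    if key not in cache:
        cache[key] = _CompiledPairs(s.elements, p, p.ground_truth_charges(s))
    return cache[key]


def _pair_key(zi: int, zj: int) -> tuple[int, int]:
    return (zi, zj) if zi <= zj else (zj, zi)


def toy_energy(s: AtomicStructure, p: ToyPotentialParams) -> float:
    """Ground-truth energy: short-range pair terms + all-pairs Coulomb."""
    e, _ = _compiled(s, p).energy_forces(s.coords, want_forces=False)
    return e


def toy_forces(s: AtomicStructure, p: ToyPotentialParams) -> np.ndarray:
    """Analytic forces -dE/dr of the ground-truth potential, kcal/mol/A."""
    _, f = _compiled(s, p).energy_forces(s.coords, want_forces=True)
    return f


def _aligned_residuals(s: AtomicStructure, b: MetaBiasParams):
    """Batched Kabsch alignment of every bias reference onto ``s``.

    Returns (delta2, diff): squared aligned RMSDs (R,) and the centered
    residuals p_c - R q_c, shape (R, N, 3).
    """
    n = s.n_atoms
    for ref in b.references:
        if not np.array_equal(ref.elements, s.elements):
            raise ValueError("bias reference has mismatched elements")
    p_c = s.coords - s.coords.mean(axis=0)
    q_all = np.stack([r.coords for r in b.references])  # (R, N, 3)
    q_c = q_all - q_all.mean(axis=1, keepdims=True)
    h = np.einsum("rni,nj->rij", q_c, p_c)  # (R, 3, 3) covariances
    u, _, vt = np.linalg.svd(h)
    det = np.sign(np.linalg.det(np.einsum("rij,rkj->rik", vt.transpose(0, 2, 1), u)))
    corr = np.broadcast_to(np.eye(3), (len(q_c), 3, 3)).copy()
    corr[:, 2, 2] = det
    rot = np.einsum("rji,rjk,rlk->ril", vt, corr, u)  # V d U^T per reference
    diff = p_c[None] - np.einsum("rij,rnj->rni", rot, q_c)
    delta2 = (diff**2).sum(axis=(1, 2)) / n
    return delta2, diff


def bias_energy(s: AtomicStructure, b: MetaBiasParams) -> float:
    """History-dependent bias sum_i k_i exp(-alpha_i Delta_i^2)."""
    if not b.references:
        return 0.0
    delta2, _ = _aligned_residuals(s, b)
    return float(np.sum(np.asarray(b.k) * np.exp(-np.asarray(b.alpha) * delta2)))


def bias_forces(s: AtomicStructure, b: MetaBiasParams) -> np.ndarray:
    """Analytic forces of the bias via the aligned-RMSD chain rule.

    dV/dr = -2 k alpha exp(-alpha D^2) / N * (p_c - R q_c); the rotation's
    dependence on the coordinates drops out at the Kabsch optimum.
    """
    if not b.references:
        return np.zeros_like(s.coords)
    delta2, diff = _aligned_residuals(s, b)
    w = (
        np.asarray(b.k)
        * np.asarray(b.alpha)
        * np.exp(-np.asarray(b.alpha) * delta2)
        * (2.0 / s.n_atoms)
    )
    return np.einsum("r,rni->ni", w, diff)


def _masses(elements: np.ndarray) -> np.ndarray:
    try:
        return np.array([_MASSES[int(z)] for z in elements])
    except KeyError as exc:  # pragma: no cover
        raise KeyError(f"no mass tabulated for element Z={exc.args[0]}") from None


def metamd_sample(
    start: AtomicStructure,
    p: ToyPotentialParams,
    k: float,
    alpha: float,
    steps: int,
    deposit_every: int,
    temperature: float = 300.0,
    timestep: float = 0.5,
    seed: int = 0,
    friction: float = 1e-3,
    frozen: np.ndarray | None = None,
    bias: MetaBiasParams | None = None,
    energy_trace: list | None = None,
) -> list[AtomicStructure]:
    """Metadynamics trajectory on the biased toy surface.

    Langevin dynamics with BAOAB splitting at ``temperature`` K, timestep
    in fs, friction in 1/fs.  Every ``deposit_every`` steps the current
    geometry is deposited as a new bias reference (strength ``k``, width
    ``alpha``) and appended to the returned trajectory, which always
    starts with ``start``.  ``k = 0`` disables the bias, giving plain
    Langevin dynamics.  ``frozen`` is an optional boolean mask of
    immobilized atoms.  Deterministic for a given seed.

    If ``energy_trace`` is a list, the total energy (potential + bias +
    kinetic, kcal/mol) after each step is appended to it — with zero
    friction and zero bias this is the conserved quantity of the
    underlying velocity-Verlet integrator.
    """
    if steps < 0:
        raise ValueError("steps must be nonnegative")
    rng = np.random.default_rng(seed)
    s = start.copy()
    traj = [start.copy()]
    if bias is None:
        bias = MetaBiasParams()
    if k > 0:
        bias.deposit(s, k, alpha)

    m = _masses(s.elements)[:, None]
    mobile = np.ones(s.n_atoms, dtype=bool) if frozen is None else ~np.asarray(frozen)
    kt = KB_KCAL * temperature
    c1 = np.exp(-friction * timestep)
    sigma = np.sqrt(kt * (1.0 - c1**2) / (m * _KCAL_PER_AMU_A2_FS2))

    # velocities from Maxwell-Boltzmann at the target temperature
    v = rng.normal(size=(s.n_atoms, 3)) * np.sqrt(
        kt / (m * _KCAL_PER_AMU_A2_FS2)
    )
    v[~mobile] = 0.0

    def total_force(struct: AtomicStructure) -> np.ndarray:
        f = toy_forces(struct, p)
        if bias.references:
            f += bias_forces(struct, bias)
        return f

    f = total_force(s)
    inv_m = 1.0 / (m * _KCAL_PER_AMU_A2_FS2)
    for step in range(1, steps + 1):
        if not np.all(np.isfinite(f)):
            raise RuntimeError(f"non-finite forces at step {step}")
        v += 0.5 * timestep * f * inv_m  # B
        v[~mobile] = 0.0
        s.coords = s.coords + 0.5 * timestep * v  # A
        noise = rng.normal(size=v.shape)
        v = c1 * v + sigma * noise  # O
        v[~mobile] = 0.0
        s.coords = s.coords + 0.5 * timestep * v  # A
        f = total_force(s)
        if not np.all(np.isfinite(f)):
            raise RuntimeError(f"non-finite forces at step {step}")
        v += 0.5 * timestep * f * inv_m  # B
        v[~mobile] = 0.0
        if energy_trace is not None:
            pe = toy_energy(s, p) + (bias_energy(s, bias) if bias.references else 0.0)
            ke = 0.5 * float(np.sum(m * v**2)) * _KCAL_PER_AMU_A2_FS2
            energy_trace.append(pe + ke)
        if deposit_every > 0 and step % deposit_every == 0:
            if k > 0:
                bias.deposit(s, k, alpha)
            traj.append(s.copy())
    return traj


# ---------------------------------------------------------------------------
# Synthetic study systems
# ---------------------------------------------------------------------------

_ELEMENT_MORSE = {  # per-element (depth kcal/mol, radius A) for mixing rules
    1: (2.0, 0.75),
    6: (4.0, 1.05),
    7: (5.0, 1.00),
    8: (6.0, 0.95),
    30: (12.0, 1.30),
}
_MORSE_WIDTH = 1.8  # 1/A, shared

_ELEMENT_CHARGES = {1: 0.10, 6: 0.05, 7: -0.30, 8: -0.40, 30: 0.80}


def default_toy_params(sr_cutoff: float = 8.0) -> ToyPotentialParams:
    """Morse+Coulomb parameters for H/C/N/O/Zn clusters.

    Pair wells use geometric-mean depths and summed radii; ground-truth
    charges follow a fixed per-element pattern (metal positive, N/O
    negative) and are shifted uniformly to match each cluster's total
    charge.
    """
    zs = sorted(_ELEMENT_MORSE)
    pair_terms: dict[tuple[int, int], list[tuple]] = {}
    for a in zs:
        for b in zs:
            if a > b:
                continue
            da, ra = _ELEMENT_MORSE[a]
            db, rb = _ELEMENT_MORSE[b]
            pair_terms[(a, b)] = [("morse", float(np.sqrt(da * db)), _MORSE_WIDTH, ra + rb)]
    return ToyPotentialParams(
        pair_terms=pair_terms,
        element_charges=dict(_ELEMENT_CHARGES),
        sr_cutoff=sr_cutoff,
    )


def make_cluster(
    rng: np.random.Generator,
    n_ligand_range: tuple[int, int] = (5, 8),
    total_charge: int = 0,
    config_id: str | None = None,
) -> AtomicStructure:
    """Random metal-centered cluster: Zn core with an H/C/N/O shell.

    First-shell atoms sit near their pair equilibrium distance from the
    metal; a second shell extends the cluster so conformers span distances
    well beyond typical local-model cutoffs.
    """
    n_lig = int(rng.integers(n_ligand_range[0], n_ligand_range[1] + 1))
    elements = [30]
    coords = [np.zeros(3)]
    shell_elems = [1, 6, 7, 8]
    for i in range(n_lig):
        z = int(rng.choice(shell_elems))
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        if i < max(3, n_lig // 2):
            r0 = _ELEMENT_MORSE[30][1] + _ELEMENT_MORSE[z][1]
            d = r0 * (1.0 + 0.08 * rng.normal())
        else:
            d = rng.uniform(3.5, 6.5)  # outer shell, beyond local cutoffs
        elements.append(z)
        coords.append(d * u)
    return AtomicStructure(
        elements=np.array(elements),
        coords=np.array(coords),
        total_charge=total_charge,
        config_id=config_id,
    )


def double_well_system() -> tuple[AtomicStructure, ToyPotentialParams, np.ndarray]:
    """A 1-atom-mobile double-well toy: O---H---O with two Morse minima.

    Two oxygen anchors 4.4 A apart are frozen; the mobile hydrogen binds
    either anchor through a deep, sharp Morse well (depth 20 kcal/mol,
    r_eq 1.6 A, width 3/A).  The two basins are separated by a ~9 kcal/mol
    barrier at the midpoint — many kT at 300 K, so unbiased dynamics stays
    trapped on the 10^4-step scale — while full escape costs ~20 kcal/mol,
    leaving the bias a wide window to drive crossings without evaporating
    the walker.  Returns (start structure, params, frozen mask); the start
    geometry sits in the first basin.
    """
    elements = np.array([8, 8, 1])
    coords = np.array([[0.0, 0.0, 0.0], [4.4, 0.0, 0.0], [1.6, 0.0, 0.0]])
    pair_terms = {
        (1, 8): [("morse", 20.0, 3.0, 1.6)],
        (8, 8): [("morse", 0.5, 1.0, 4.4)],
        (1, 1): [("morse", 0.1, 1.0, 2.0)],
    }
    p = ToyPotentialParams(pair_terms=pair_terms, element_charges={}, sr_cutoff=10.0)
    frozen = np.array([True, True, False])
    start = AtomicStructure(elements, coords, 0)
    return start, p, frozen


def generate_dataset(
    n_configs: int,
    per_config: int,
    p: ToyPotentialParams | None = None,
    schedule: Sequence[tuple[float, float]] = ((2.0, 1.0), (5.0, 0.5)),
    seed: int = 0,
    deposit_every: int = 40,
    temperature: float = 300.0,
    timestep: float = 0.5,
    dedup_cutoff: float = 0.1,
    n_ligand_range: tuple[int, int] = (5, 8),
    steps_per_run: int | None = None,
) -> list[ConformerEnsemble]:
    """Generate labeled conformer ensembles of random clusters.

    For each of ``n_configs`` random clusters, one metadynamics run per
    ``(k, alpha)`` schedule entry is performed (``per_config`` deposits
    each, i.e. ``per_config * deposit_every`` steps unless
    ``steps_per_run`` overrides it), trajectories are pooled,
    near-duplicates removed at ``dedup_cutoff`` A, and every survivor is
    labeled with its ground-truth energy.  Deterministic for a given seed.
    """
    from .geometry import deduplicate

    if n_configs < 1:
        raise ValueError("need at least one configuration")
    if p is None:
        p = default_toy_params()
    rng = np.random.default_rng(seed)
    ensembles: list[ConformerEnsemble] = []
    for c in range(n_configs):
        cid = f"config_{c:04d}"
        start = make_cluster(rng, n_ligand_range=n_ligand_range, config_id=cid)
        pool: list[AtomicStructure] = [start.copy()]
        for run, (k, alpha) in enumerate(schedule):
            traj = metamd_sample(
                start,
                p,
                k=k,
                alpha=alpha,
                steps=(steps_per_run if steps_per_run is not None
                       else per_config * deposit_every),
                deposit_every=deposit_every,
                temperature=temperature,
                timestep=timestep,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            pool.extend(t for t in traj[1:])  # start already pooled once
        for idx, s in enumerate(pool):
            s.config_id = cid
            s.struct_id = f"{cid}_m{idx:03d}"
        ens = deduplicate(ConformerEnsemble(cid, pool), cutoff=dedup_cutoff)
        for s in ens.members:
            s.energy = toy_energy(s, p)
        ensembles.append(ens)
    return ensembles
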