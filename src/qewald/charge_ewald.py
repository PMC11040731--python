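"""Charge-constrained Ewald message passing.

The long-range branch of the model.  Initial nuclear embeddings are mapped
to raw per-atom charges by a small network, the charges are scaled so they
sum exactly to the system's total charge Q,

    q_i = q~_i + (Q - sum_j q~_j) / N,

lifted to F-dimensional charge embeddings through a learned lift plus a
two-layer residual block, and exchanged between *all* atoms (no distance
cutoff) through a band-limited kernel built from a few low frequencies.

Two equivalent realizations of the long-range messages are provided:

``direct_radial`` (reference semantics)
    m_i = sum_j K(|r_i - r_j|) * c_j  with  K(d) = sum_m w_m sinc(k_m d),
    a rotation-invariant radial kernel (sinc(x) = sin(x)/x, value 1 at 0).

``plane_wave`` (factorized approximation)
    For a set of unit directions u, structure factors
    S_cos = sum_j cos(k_m u.r_j) c_j (and sin alike) give
    m_i = (1/M) sum_u sum_m w_m * [cos(k_m u.r_i) S_cos + sin(k_m u.r_i) S_sin],
    an O(N M K) sum whose direction average converges to the radial kernel
    as the direction set fills the sphere.

With the long-range filter weights w_m at zero the whole branch vanishes
and the model reduces exactly to the short-range baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, as_tensor, segment_sum
from .nnp_core import (
    BaselineParams,
    StructureBatch,
    AtomEmbeddings,
    baseline_atomic_embeddings,
    embed,
    readout_energy,
)
from .structures import AtomicStructure

__all__ = [
    "ChargeHead",
    "FourierGrid",
    "ModelConfig",
    "FullModelParams",
    "direction_set",
    "predict_raw_charges",
    "scale_charges",
    "charge_embedding",
    "ewald_messages",
    "full_forward",
    "predicted_charges",
]


def _xavier(rng, fan_in, fan_out):
    scale = np.sqrt(2.0 / (fan_in + fan_out))
    return Tensor(rng.normal(0.0, scale, size=(fan_in, fan_out)), requires_grad=True)


def _zeros(*shape):
    return Tensor(np.zeros(shape), requires_grad=True)


@dataclass
class ChargeHead:
    """Charge network (embeddings -> raw charges) and the charge lift."""

    w1: Tensor  # (F, H)
    b1: Tensor
    w2: Tensor  # (H, 1)
    b2: Tensor
    lift: Tensor  # (F,) learned direction scaled by the charge
    w_res1: Tensor  # (F, F) two-layer residual block on the lifted charge
    b_res1: Tensor
    w_res2: Tensor  # (F, F)
    b_res2: Tensor

    @classmethod
    def init(cls, rng: np.random.Generator, n_features: int, hidden: int = 32):
        return cls(
            w1=_xavier(rng, n_features, hidden),
            b1=_zeros(hidden),
            w2=_xavier(rng, hidden, 1),
            b2=_zeros(1),
            lift=Tensor(rng.normal(0.0, 1.0, size=(n_features,)), requires_grad=True),
            w_res1=_xavier(rng, n_features, n_features),
            b_res1=_zeros(n_features),
            w_res2=_xavier(rng, n_features, n_features),
            b_res2=_zeros(n_features),
        )

    def parameters(self):
        return [
            self.w1, self.b1, self.w2, self.b2, self.lift,
            self.w_res1, self.b_res1, self.w_res2, self.b_res2,
        ]


def direction_set(m: int) -> np.ndarray:
    """Quasi-uniform, inversion-symmetric unit directions on the sphere.

    m=6 gives the octahedron vertices, m=26 the full {-1,0,1}^3 shell;
    any other even m uses an antipodally symmetrized Fibonacci lattice.
    """
    if m == 6:
        dirs = np.concatenate([np.eye(3), -np.eye(3)])
    elif m == 26:
        grid = np.array(
            [
                (i, j, k)
                for i in (-1, 0, 1)
                for j in (-1, 0, 1)
                for k in (-1, 0, 1)
                if (i, j, k) != (0, 0, 0)
            ],
            dtype=float,
        )
        dirs = grid / np.linalg.norm(grid, axis=1, keepdims=True)
    else:
        if m % 2 != 0 or m < 2:
            raise ValueError("direction count must be even and >= 2")
        half = m // 2
        # Fibonacci points on the upper hemisphere, then add antipodes
        golden = (1.0 + np.sqrt(5.0)) / 2.0
        idx = np.arange(half)
        z = (idx + 0.5) / half  # z in (0, 1): upper hemisphere
        phi = 2.0 * np.pi * idx / golden
        r = np.sqrt(1.0 - z**2)
        upper = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
        dirs = np.concatenate([upper, -upper])
    return dirs


@dataclass
class FourierGrid:
    """Band-limited kernel: frequencies, learnable filters, direction set."""

    n_frequencies: int = 8
    k_cutoff: float = 2.0  # 1/A
    mode: str = "direct_radial"  # or "plane_wave"
    n_directions: int = 26
    weights: Tensor | None = None  # (n_frequencies, F)

    def __post_init__(self):
        if self.n_frequencies < 1:
            raise ValueError("need at least one frequency")
        if self.mode not in ("direct_radial", "plane_wave"):
            raise ValueError(f"unknown ewald mode {self.mode!r}")
        self.frequencies = (
            self.k_cutoff * np.arange(1, self.n_frequencies + 1) / self.n_frequencies
        )
        self.directions = (
            direction_set(self.n_directions) if self.mode == "plane_wave" else None
        )

    @classmethod
    def init(
        cls,
        rng: np.random.Generator,
        n_features: int,
        n_frequencies: int = 8,
        k_cutoff: float = 2.0,
        mode: str = "direct_radial",
        n_directions: int = 26,
        zero_weights: bool = False,
    ):
        g = cls(n_frequencies, k_cutoff, mode, n_directions)
        if zero_weights:
            g.weights = _zeros(n_frequencies, n_features)
        else:
            g.weights = _xavier(rng, n_frequencies, n_features)
        return g

    def parameters(self):
        return [self.weights] if self.weights is not None else []


@dataclass
class ModelConfig:
    """Hyperparameters of the composed model.

    variant: 'baseline' (short-range only), 'ewald' (long-range branch on
    nuclear embeddings), or 'ewald_q' (long-range branch on the
    charge-constrained embeddings).
    """

    variant: str = "ewald_q"
    n_features: int = 64
    n_blocks: int = 3
    n_rbf: int = 32
    cutoff: float = 5.0
    charge_hidden: int = 32
    ewald_mode: str = "direct_radial"
    ewald_n_frequencies: int = 8
    ewald_k_cutoff: float = 2.0
    ewald_n_directions: int = 26

    def __post_init__(self):
        if self.variant not in ("baseline", "ewald", "ewald_q"):
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass
class FullModelParams:
    """Baseline plus (optionally) the charge head and Ewald branch."""

    config: ModelConfig
    baseline: BaselineParams
    charge_head: ChargeHead | None = None
    grid: FourierGrid | None = None
    w_project: Tensor | None = None  # (F, F), zero-init: ablation identity

    @classmethod
    def init(cls, config: ModelConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        baseline = BaselineParams.init(
            rng,
            n_features=config.n_features,
            n_blocks=config.n_blocks,
            n_rbf=config.n_rbf,
            cutoff=config.cutoff,
        )
        head = grid = w_project = None
        if config.variant != "baseline":
            head = ChargeHead.init(rng, config.n_features, config.charge_hidden)
            grid = FourierGrid.init(
                rng,
                config.n_features,
                n_frequencies=config.ewald_n_frequencies,
                k_cutoff=config.ewald_k_cutoff,
                mode=config.ewald_mode,
                n_directions=config.ewald_n_directions,
            )
            w_project = _zeros(config.n_features, config.n_features)
        return cls(config, baseline, head, grid, w_project)

    def parameters(self) -> list[Tensor]:
        ps = self.baseline.parameters()
        if self.charge_head is not None and self.config.variant == "ewald_q":
            ps.extend(self.charge_head.parameters())
        if self.grid is not None:
            ps.extend(self.grid.parameters())
        if self.w_project is not None:
            ps.append(self.w_project)
        return ps

    # -- text checkpointing ----------------------------------------------
    def state_dict(self) -> dict:
        import dataclasses

        named = {}

        def put(prefix, obj):
            for f in dataclasses.fields(obj):
                v = getattr(obj, f.name)
                if isinstance(v, Tensor):
                    named[f"{prefix}{f.name}"] = v

        put("baseline.", self.baseline)
        for i, blk in enumerate(self.baseline.blocks):
            put(f"baseline.blocks.{i}.", blk)
        put("baseline.readout.", self.baseline.readout)
        if self.charge_head is not None:
            put("charge_head.", self.charge_head)
        if self.grid is not None and self.grid.weights is not None:
            named["grid.weights"] = self.grid.weights
        if self.w_project is not None:
            named["w_project"] = self.w_project
        return {
            "config": dataclasses.asdict(self.config),
            "weights": {k: v.data.tolist() for k, v in named.items()},
            "shapes": {k: list(v.data.shape) for k, v in named.items()},
        }

    def load_state_dict(self, state: dict) -> None:
        import dataclasses

        named = {}

        def put(prefix, obj):
            for f in dataclasses.fields(obj):
                v = getattr(obj, f.name)
                if isinstance(v, Tensor):
                    named[f"{prefix}{f.name}"] = v

        put("baseline.", self.baseline)
        for i, blk in enumerate(self.baseline.blocks):
            put(f"baseline.blocks.{i}.", blk)
        put("baseline.readout.", self.baseline.readout)
        if self.charge_head is not None:
            put("charge_head.", self.charge_head)
        if self.grid is not None and self.grid.weights is not None:
            named["grid.weights"] = self.grid.weights
        if self.w_project is not None:
            named["w_project"] = self.w_project
        for k, t in named.items():
            arr = np.asarray(state["weights"][k], dtype=np.float64)
            if arr.shape != t.data.shape:
                raise ValueError(
                    f"checkpoint shape mismatch for {k}: "
                    f"{arr.shape} vs {t.data.shape}"
                )
            t.data = arr

    def save(self, path) -> None:
        import json
        from pathlib import Path

        Path(path).write_text(json.dumps(self.state_dict()))

    @classmethod
    def load(cls, path) -> "FullModelParams":
        import json
        from pathlib import Path

        state = json.loads(Path(path).read_text())
        config = ModelConfig(**state["config"])
        params = cls.init(config, seed=0)
        params.load_state_dict(state)
        return params


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def predict_raw_charges(x: AtomEmbeddings, head: ChargeHead) -> Tensor:
    """Unconstrained per-atom charges q~ from nuclear embeddings, (N,)."""
    h = ((x.x @ head.w1) + head.b1).ssp() @ head.w2 + head.b2
    return h.reshape(-1)


def scale_charges(q_raw, total_charge, seg: np.ndarray | None = None,
                  n_structures: int = 1) -> Tensor:
    """Shift raw charges so each structure's charges sum exactly to Q.

    q_i = q~_i + (Q - sum q~)/N, the uniform redistribution of the charge
    deficit; differentiable and exact.  ``seg`` enables batched use.
    """
    q_raw = as_tensor(q_raw)
    n_tot = q_raw.shape[0]
    if seg is None:
        seg = np.zeros(n_tot, dtype=np.intp)
    counts = np.bincount(seg, minlength=n_structures).astype(np.float64)
    q_target = np.broadcast_to(
        np.asarray(total_charge, dtype=np.float64), (n_structures,)
    )
    sums = segment_sum(q_raw, seg, n_structures)  # (S,)
    deficit = (Tensor(q_target) - sums) / Tensor(counts)
    return q_raw + deficit.gather(seg)


def charge_embedding(q, head: ChargeHead) -> Tensor:
    """Lift scalar charges to F dims: c = P(q) + MLP2(P(q)), P(q) = q*lift."""
    q = as_tensor(q)
    p = q.reshape(-1, 1) * head.lift.reshape(1, -1)  # (N, F)
    res = ((p @ head.w_res1) + head.b_res1).ssp() @ head.w_res2 + head.b_res2
    return p + res


def _intra_structure_pairs(seg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All ordered pairs (i != j) within each segment."""
    ii, jj = [], []
    for s in np.unique(seg):
        idx = np.nonzero(seg == s)[0]
        a, b = np.meshgrid(idx, idx, indexing="ij")
        keep = a.ravel() != b.ravel()
        ii.append(a.ravel()[keep])
        jj.append(b.ravel()[keep])
    return np.concatenate(ii), np.concatenate(jj)


def ewald_messages(
    c: Tensor,
    coords,
    grid: FourierGrid,
    seg: np.ndarray | None = None,
    n_structures: int = 1,
) -> Tensor:
    """Long-range messages from charge embeddings, (N, F).

    See the module docstring for the two modes.  ``seg`` restricts the
    all-pairs sums to atoms of the same structure when batching.
    """
    if grid.weights is None:
        raise ValueError("FourierGrid has no filter weights")
    if len(grid.frequencies) == 0:
        raise ValueError("empty frequency list")
    c = as_tensor(c)
    coords = as_tensor(coords)
    n = c.shape[0]
    if seg is None:
        seg = np.zeros(n, dtype=np.intp)
    if grid.mode == "direct_radial":
        # self term separately: K(0) = sum_m w_m (sinc -> 1), avoiding the
        # non-differentiable sqrt at d = 0
        w_sum = grid.weights.sum(axis=0).reshape(1, -1)  # (1, F)
        out = c * w_sum
        pi, pj = _intra_structure_pairs(seg)
        if len(pi):
            ri = coords.gather(pi)
            rj = coords.gather(pj)
            diff = ri - rj
            d = (diff * diff).sum(axis=1, keepdims=True).sqrt()  # (P,1)
            x = d * Tensor(grid.frequencies.reshape(1, -1))  # (P, K)
            kernel = x.sinc() @ grid.weights  # (P, F)
            out = out + segment_sum(kernel * c.gather(pj), pi, n)
        return out
    # plane_wave: factorized structure-factor form
    dirs = grid.directions
    m_dirs = len(dirs)
    proj = coords @ Tensor(dirs.T)  # (N, M)
    out = None
    for m, k_m in enumerate(grid.frequencies):
        phase = proj * float(k_m)  # (N, M)
        cph = phase.cos().reshape(n, m_dirs, 1)
        sph = phase.sin().reshape(n, m_dirs, 1)
        c3 = c.reshape(n, 1, -1)
        s_cos = segment_sum(cph * c3, seg, n_structures)  # (S, M, F)
        s_sin = segment_sum(sph * c3, seg, n_structures)
        msg = cph * s_cos.gather(seg) + sph * s_sin.gather(seg)  # (N, M, F)
        msg = msg.mean(axis=1)  # direction average, (N, F)
        w_m = grid.weights.gather(np.array([m])).reshape(1, -1)
        term = msg * w_m
        out = term if out is None else out + term
    return out


def model_energies(batch: StructureBatch, params: FullModelParams) -> Tensor:
    """Per-structure total energies (n_structures,) for any variant."""
    cfg = params.config
    x0 = embed(batch.elements, params.baseline.embedding)
    h = x0
    d = batch.pair_distances()
    for blk in params.baseline.blocks:
        from .nnp_core import interaction_step

        h = interaction_step(h, batch, params.baseline.rbf, blk, d=d)
    if cfg.variant != "baseline":
        if cfg.variant == "ewald_q":
            q_raw = predict_raw_charges(x0, params.charge_head)
            q = scale_charges(
                q_raw, batch.total_charges, seg=batch.seg,
                n_structures=batch.n_structures,
            )
            c = charge_embedding(q, params.charge_head)
        else:  # 'ewald': nuclear embeddings straight into the long-range block
            c = x0.x
        msgs = ewald_messages(
            c, batch.coords, params.grid, seg=batch.seg,
            n_structures=batch.n_structures,
        )
        h = AtomEmbeddings(h.x + msgs @ params.w_project)
    _, totals = readout_energy(
        h, batch.elements, params.baseline.readout,
        seg=batch.seg, n_structures=batch.n_structures,
    )
    return totals


def full_forward(s: AtomicStructure, params: FullModelParams) -> float:
    """Total predicted energy of one structure, kcal/mol."""
    batch = StructureBatch.from_structures([s], params.config.cutoff)
    return float(model_energies(batch, params).data[0])


def predicted_charges(s: AtomicStructure, params: FullModelParams) -> np.ndarray:
    """Constrained partial charges (e) the model assigns to one structure."""
    if params.charge_head is None:
        raise ValueError("model variant has no charge head")
    x0 = embed(s.elements, params.baseline.embedding)
    q_raw = predict_raw_charges(x0, params.charge_head)
    q = scale_charges(q_raw, float(s.total_charge))
    return q.data.copy()
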