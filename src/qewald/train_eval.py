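"""Training loop and the conformer-energy evaluation protocol.

Training is minibatch Adam on the total-energy loss (MSE by default, MAE
reported) with either a milestone-warmup learning-rate schedule — lr
starts at ``warmup_factor`` x base, ramps linearly to base over
``warmup_steps``, then is multiplied by ``decay_factor`` at each decay
milestone — or a plateau schedule that halves the rate after ``patience``
validation checks without improvement.  The best-on-validation checkpoint
is returned.

Evaluation mirrors the standard conformer-benchmark protocol: MAE of total
energies, Pearson correlation of relative conformational energies, and the
misranking count — per ensemble, the conformer with the lowest *reference*
energy is the most stable; every other conformer whose *test* energy falls
strictly below the test energy of that reference conformer counts as
misranked, summed over all ensembles with at least two members.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .autodiff import Tensor
from .charge_ewald import FullModelParams, ModelConfig, model_energies
from .nnp_core import StructureBatch
from .structures import AtomicStructure, ConformerEnsemble

__all__ = [
    "TrainConfig",
    "TrainResult",
    "EvalReport",
    "learning_rate_at",
    "train",
    "evaluate_mae",
    "relative_energies",
    "misranking_count",
    "pearson_r",
    "evaluate_report",
    "ablation_study",
    "init_element_offsets",
]


@dataclass
class TrainConfig:
    """Optimization settings.

    Defaults mirror a standard schedule for this model family: base
    learning rate 5e-4, batch size 64, 30,000 warmup steps at factor 0.2,
    decays at 60,000/90,000/120,000 steps by 0.1.  Desk-scale runs override
    ``max_steps`` and the milestones.
    """

    learning_rate: float = 5e-4
    batch_size: int = 64
    scheduler: str = "milestone_warmup"  # or "plateau"
    warmup_steps: int = 30_000
    warmup_factor: float = 0.2
    decay_steps: tuple[int, ...] = (60_000, 90_000, 120_000)
    decay_factor: float = 0.1
    plateau_patience: int = 10
    plateau_factor: float = 0.5
    max_steps: int = 150_000
    eval_every: int | None = None  # default: max_steps // 20
    loss: str = "mse"  # or "mae"
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if list(self.decay_steps) != sorted(self.decay_steps):
            raise ValueError("decay_steps must be increasing")
        if self.loss not in ("mse", "mae"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.scheduler not in ("milestone_warmup", "plateau"):
            raise ValueError(f"unknown scheduler {self.scheduler!r}")


@dataclass
class TrainResult:
    """Trained parameters plus the optimization trace."""

    params: FullModelParams
    loss_history: np.ndarray
    lr_history: np.ndarray
    val_history: list[tuple[int, float]]
    best_step: int
    best_val_mae: float


@dataclass
class EvalReport:
    """Conformer-benchmark metrics on a labeled set."""

    mae: float
    pearson_r: float
    misranking_count: int
    n_structures: int
    n_ensembles_ranked: int
    relative_tables: list[tuple[str, np.ndarray, np.ndarray]] = field(
        default_factory=list
    )  # (config_id, reference dE, predicted dE)

    def to_dict(self) -> dict:
        return {
            "mae": self.mae,
            "pearson_r": self.pearson_r,
            "misranking_count": self.misranking_count,
            "n_structures": self.n_structures,
            "n_ensembles_ranked": self.n_ensembles_ranked,
        }

    def summary(self) -> str:
        lines = [
            "Conformer-energy evaluation",
            "---------------------------",
            f"structures evaluated     : {self.n_structures}",
            f"MAE (kcal/mol)           : {self.mae:.4f}",
            f"Pearson r (relative E)   : {self.pearson_r:.4f}",
            f"ensembles ranked (>=2)   : {self.n_ensembles_ranked}",
            f"misranking count         : {self.misranking_count}",
        ]
        return "\n".join(lines)


def learning_rate_at(step: int, cfg: TrainConfig) -> float:
    """Closed-form milestone-warmup learning rate at a given step."""
    base = cfg.learning_rate
    if cfg.warmup_steps > 0:
        ramp = min(step / cfg.warmup_steps, 1.0)
    else:
        ramp = 1.0
    lr = base * (cfg.warmup_factor + (1.0 - cfg.warmup_factor) * ramp)
    for ds in cfg.decay_steps:
        if step >= ds:
            lr *= cfg.decay_factor
    return lr


class _Adam:
    def __init__(self, params: list[Tensor], beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data = p.data - lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def _labels(structures: Sequence[AtomicStructure]) -> np.ndarray:
    labels = [s.energy for s in structures]
    if any(e is None for e in labels):
        raise ValueError("all structures must carry an energy label")
    return np.array(labels, dtype=np.float64)


def init_element_offsets(
    params: FullModelParams, structures: Sequence[AtomicStructure]
) -> None:
    """Least-squares per-element reference energies into the readout offsets.

    Regressing total energies on element counts absorbs the (large,
    conformation-independent) atomic contributions so the network only has
    to learn relative energetics.  Standard practice for energy models.
    """
    from .nnp_core import MAX_Z

    labels = _labels(structures)
    counts = np.zeros((len(structures), MAX_Z + 1))
    for k, s in enumerate(structures):
        for z in s.elements:
            counts[k, int(z)] += 1
    coef, *_ = np.linalg.lstsq(counts, labels, rcond=None)
    used = counts.sum(axis=0) > 0
    offsets = np.zeros((MAX_Z + 1, 1))
    offsets[used, 0] = coef[used]
    params.baseline.readout.offsets.data = offsets


def train(
    params: FullModelParams,
    train_structures: Sequence[AtomicStructure],
    val_structures: Sequence[AtomicStructure],
    cfg: TrainConfig,
) -> TrainResult:
    """Minibatch training; returns the best-on-validation checkpoint."""
    if not train_structures or not val_structures:
        raise ValueError("train and validation sets must be nonempty")
    rng = np.random.default_rng(cfg.seed)
    y_train = _labels(train_structures)
    trainable = params.parameters()
    opt = _Adam(trainable)
    eval_every = cfg.eval_every or max(cfg.max_steps // 20, 1)

    loss_hist = np.empty(cfg.max_steps)
    lr_hist = np.empty(cfg.max_steps)
    val_hist: list[tuple[int, float]] = []
    best = {
        "mae": math.inf,
        "step": 0,
        "state": [p.data.copy() for p in trainable],
    }
    lr_plateau = cfg.learning_rate
    bad_checks = 0

    # pre-build one batch object per unique minibatch to amortize neighbor
    # lists: sample indices fresh each step, cache by tuple
    cache: dict[tuple, tuple[StructureBatch, np.ndarray]] = {}

    for step in range(1, cfg.max_steps + 1):
        idx = rng.choice(len(train_structures), size=min(
            cfg.batch_size, len(train_structures)), replace=False)
        key = tuple(idx.tolist())
        if key in cache:
            batch, y = cache[key]
        else:
            batch = StructureBatch.from_structures(
                [train_structures[i] for i in idx], params.config.cutoff
            )
            y = y_train[idx]
            if len(cache) < 4096:
                cache[key] = (batch, y)
        pred = model_energies(batch, params)
        diff = pred - Tensor(y)
        if cfg.loss == "mse":
            loss = (diff * diff).mean()
        else:  # smooth |x| = sqrt(x^2 + eps) keeps the gradient finite at 0
            loss = ((diff * diff + 1e-12) ** 0.5).mean()
        if not np.isfinite(loss.data):
            raise RuntimeError(f"training diverged: non-finite loss at step {step}")
        opt.zero_grad()
        loss.backward()
        if cfg.scheduler == "milestone_warmup":
            lr = learning_rate_at(step, cfg)
        else:
            lr = lr_plateau
        opt.step(lr)
        loss_hist[step - 1] = float(loss.data)
        lr_hist[step - 1] = lr

        if step % eval_every == 0 or step == cfg.max_steps:
            val_mae = evaluate_mae(params, val_structures)
            val_hist.append((step, val_mae))
            if val_mae < best["mae"]:
                best = {
                    "mae": val_mae,
                    "step": step,
                    "state": [p.data.copy() for p in trainable],
                }
                bad_checks = 0
            else:
                bad_checks += 1
                if cfg.scheduler == "plateau" and bad_checks >= cfg.plateau_patience:
                    lr_plateau *= cfg.plateau_factor
                    bad_checks = 0

    for p, saved in zip(trainable, best["state"]):
        p.data = saved
    return TrainResult(
        params=params,
        loss_history=loss_hist,
        lr_history=lr_hist,
        val_history=val_hist,
        best_step=best["step"],
        best_val_mae=best["mae"],
    )


def predict_energies(
    params: FullModelParams, structures: Sequence[AtomicStructure],
    chunk: int = 64,
) -> np.ndarray:
    """Model energies for a list of structures, kcal/mol."""
    out = np.empty(len(structures))
    for lo in range(0, len(structures), chunk):
        part = structures[lo : lo + chunk]
        batch = StructureBatch.from_structures(part, params.config.cutoff)
        out[lo : lo + len(part)] = model_energies(batch, params).data
    return out


def evaluate_mae(
    params: FullModelParams, structures: Sequence[AtomicStructure]
) -> float:
    """Mean absolute error |E_pred - E_ref| over labeled structures."""
    if not structures:
        raise ValueError("cannot evaluate on an empty set")
    y = _labels(structures)
    pred = predict_energies(params, structures)
    return float(np.mean(np.abs(pred - y)))


def relative_energies(energies: Sequence[float]) -> np.ndarray:
    """Energies relative to the ensemble minimum; the minimum maps to 0."""
    e = np.asarray(energies, dtype=np.float64)
    if e.size < 1:
        raise ValueError("need at least one energy")
    return e - e.min()


def misranking_count(
    ensembles: Sequence[tuple[Sequence[float], Sequence[float]]],
) -> int:
    """Conformers a test method ranks below the reference-best conformer.

    ``ensembles`` holds (reference_energies, test_energies) pairs per
    ensemble.  In each ensemble with >= 2 members, the argmin of the
    reference energies is the most stable conformer; every other conformer
    whose test energy is strictly lower than the test energy of that
    conformer is counted.  Singleton ensembles are skipped.
    """
    total = 0
    for ref, test in ensembles:
        ref = np.asarray(ref, dtype=np.float64)
        test = np.asarray(test, dtype=np.float64)
        if len(ref) != len(test):
            raise ValueError("reference and test energies differ in length")
        if len(ref) < 2:
            continue
        r_star = int(np.argmin(ref))
        below = test < test[r_star]
        below[r_star] = False
        total += int(below.sum())
    return total


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need two equal-length sequences of length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def evaluate_report(
    params: FullModelParams, ensembles: Sequence[ConformerEnsemble]
) -> EvalReport:
    """Full conformer-benchmark report on labeled ensembles."""
    structures = [s for e in ensembles for s in e.members]
    y = _labels(structures)
    pred = predict_energies(params, structures)
    mae = float(np.mean(np.abs(pred - y)))

    tables = []
    rank_pairs = []
    rel_ref_all, rel_pred_all = [], []
    pos = 0
    for e in ensembles:
        n = len(e)
        ref = y[pos : pos + n]
        hat = pred[pos : pos + n]
        pos += n
        if n >= 2:
            dref = relative_energies(ref)
            dhat = hat - hat[int(np.argmin(ref))]
            tables.append((e.configuration_id, dref, dhat))
            rank_pairs.append((ref, hat))
            rel_ref_all.append(dref)
            rel_pred_all.append(dhat)
    if rel_ref_all:
        rr = np.concatenate(rel_ref_all)
        rp = np.concatenate(rel_pred_all)
        r = pearson_r(rr, rp) if np.ptp(rr) > 0 and np.ptp(rp) > 0 else float("nan")
    else:
        r = float("nan")
    return EvalReport(
        mae=mae,
        pearson_r=r,
        misranking_count=misranking_count(rank_pairs),
        n_structures=len(structures),
        n_ensembles_ranked=len(rank_pairs),
        relative_tables=tables,
    )


def ablation_study(
    ensembles: Sequence[ConformerEnsemble],
    seeds: Sequence[int],
    base_config: ModelConfig,
    train_cfg: TrainConfig,
    variants: Sequence[str] = ("baseline", "ewald", "ewald_q"),
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
) -> dict:
    """Train each model variant per seed with identical budgets.

    Returns ``{"per_seed": {variant: [mae, ...]}, "median": {variant: m}}``
    test MAEs; the split and the training budget are shared across
    variants so differences isolate the long-range branch.
    """
    from dataclasses import replace as _replace

    from .structures import random_split

    structures = [s for e in ensembles for s in e.members]
    per_seed: dict[str, list[float]] = {v: [] for v in variants}
    for seed in seeds:
        split = random_split(len(structures), split_fractions, seed=seed)
        tr = [structures[i] for i in split.train_idx]
        va = [structures[i] for i in split.val_idx]
        te = [structures[i] for i in split.test_idx]
        for variant in variants:
            cfg_v = _replace(base_config, variant=variant)
            params = FullModelParams.init(cfg_v, seed=seed)
            init_element_offsets(params, tr)
            result = train(params, tr, va, _replace(train_cfg, seed=seed))
            per_seed[variant].append(evaluate_mae(result.params, te))
    return {
        "per_seed": per_seed,
        "median": {v: float(np.median(per_seed[v])) for v in variants},
    }
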