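"""Frozen desk-scale study protocols.

These are the standard conditions under which the package's claims are
demonstrated end-to-end on a single CPU in minutes: the synthetic data
set, the tiny model, the shared training budget of the three-variant
ablation, and the double-well metadynamics contrast.  Tests and the
reproduction script import them so every entry point runs the same
experiment.
"""

from __future__ import annotations

from .charge_ewald import ModelConfig
from .train_eval import TrainConfig

__all__ = [
    "ablation_model_config",
    "ablation_train_config",
    "ABLATION_DATASET",
    "DOUBLE_WELL_BIAS",
]

# synthetic data set: 50 random Zn-centered clusters, two metadynamics
# runs each (moderate and strong pushing), ~10 conformers per ensemble
ABLATION_DATASET = dict(
    n_configs=50,
    per_config=5,
    schedule=((2.0, 1.0), (5.0, 0.5)),
    deposit_every=40,
)

# double-well rare-event toy: weak, narrow Gaussians deposited frequently
# cross the ~9 kcal/mol inter-basin barrier without evaporating the walker
DOUBLE_WELL_BIAS = dict(k=0.5, alpha=8.0, deposit_every=50, steps=10_000)


def ablation_model_config(variant: str = "ewald_q") -> ModelConfig:
    """Tiny model used for the CPU-scale ablation (16 features, 2 blocks)."""
    return ModelConfig(
        variant=variant,
        n_features=16,
        n_blocks=2,
        n_rbf=8,
        cutoff=3.0,
        charge_hidden=16,
        ewald_n_frequencies=4,
    )


def ablation_train_config(max_steps: int = 2500) -> TrainConfig:
    """Shared training budget for all ablation variants."""
    return TrainConfig(
        learning_rate=1e-3,
        batch_size=16,
        max_steps=max_steps,
        warmup_steps=max_steps // 5,
        decay_steps=(int(max_steps * 0.6), int(max_steps * 0.84)),
        decay_factor=0.3,
    )
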