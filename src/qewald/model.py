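"""Model/Results front end for fitting a potential to conformer data.

This is the convenience layer most users interact with::

    from qewald import ConformerEnergyModel
    model = ConformerEnergyModel(ensembles, variant="ewald_q")
    res = model.fit(max_steps=2000)
    print(res.summary())

The heavy lifting lives in :mod:`qewald.train_eval`; this module only
packages data handling (splits, offset initialization), fitting, and
reporting into a model object and a results object.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np

from .charge_ewald import FullModelParams, ModelConfig, predicted_charges
from .structures import (
    AtomicStructure,
    ConformerEnsemble,
    DatasetSplit,
    group_into_ensembles,
    random_split,
    read_extxyz,
)
from .train_eval import (
    EvalReport,
    TrainConfig,
    TrainResult,
    evaluate_mae,
    evaluate_report,
    init_element_offsets,
    predict_energies,
    train,
)

__all__ = ["ConformerEnergyModel", "ConformerEnergyResult"]


class ConformerEnergyModel:
    """A potential-energy model bound to a labeled conformer data set.

    Parameters
    ----------
    data : list of ConformerEnsemble or list of AtomicStructure
        Labeled conformers; plain structure lists are grouped into
        ensembles by their config_id tag.
    variant : {'baseline', 'ewald', 'ewald_q'}
        Short-range only, long-range branch fed by nuclear embeddings, or
        long-range branch fed by total-charge-constrained partial charges.
    split_fractions : (train, val, test) fractions for the random split.
    seed : controls the split, the weight init and the training shuffles.
    config / train_config : full hyperparameter objects; keyword
        overrides passed to :meth:`fit` are applied on top.
    """

    def __init__(
        self,
        data: Sequence[ConformerEnsemble] | Sequence[AtomicStructure],
        variant: str = "ewald_q",
        config: ModelConfig | None = None,
        train_config: TrainConfig | None = None,
        split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
        seed: int = 0,
    ):
        data = list(data)
        if data and isinstance(data[0], AtomicStructure):
            self.ensembles = group_into_ensembles(data)
        else:
            self.ensembles = list(data)
        self.structures = [s for e in self.ensembles for s in e.members]
        if len(self.structures) < 3:
            raise ValueError("need at least 3 labeled structures")
        self.config = (
            replace(config, variant=variant) if config is not None
            else ModelConfig(variant=variant)
        )
        self.train_config = train_config or TrainConfig()
        self.seed = seed
        self.split: DatasetSplit = random_split(
            len(self.structures), split_fractions, seed=seed
        )

    @classmethod
    def from_extxyz(cls, path, **kwargs) -> "ConformerEnergyModel":
        """Build the model from a labeled extended-XYZ file."""
        return cls(read_extxyz(path), **kwargs)

    def _subset(self, idx: np.ndarray) -> list[AtomicStructure]:
        return [self.structures[i] for i in idx]

    def fit(self, **overrides) -> "ConformerEnergyResult":
        """Train and return the fitted result.

        Keyword overrides are applied to the training config (e.g.
        ``max_steps=2000, batch_size=16``).
        """
        cfg = replace(self.train_config, seed=self.seed, **overrides)
        params = FullModelParams.init(self.config, seed=self.seed)
        tr = self._subset(self.split.train_idx)
        va = self._subset(self.split.val_idx)
        init_element_offsets(params, tr)
        result = train(params, tr, va, cfg)
        return ConformerEnergyResult(self, result)


class ConformerEnergyResult:
    """Fitted potential: parameters, optimization trace, and diagnostics."""

    def __init__(self, model: ConformerEnergyModel, train_result: TrainResult):
        self.model = model
        self.train_result = train_result
        self.params = train_result.params
        self._test_report: EvalReport | None = None

    # -- prediction -------------------------------------------------------
    def predict(self, structures: Sequence[AtomicStructure]) -> np.ndarray:
        """Predicted total energies, kcal/mol."""
        return predict_energies(self.params, structures)

    def partial_charges(self, s: AtomicStructure) -> np.ndarray:
        """Constrained partial charges (e); requires a charged variant."""
        return predicted_charges(s, self.params)

    # -- diagnostics ------------------------------------------------------
    @property
    def test_ensembles(self) -> list[ConformerEnsemble]:
        """The held-out test structures, regrouped into ensembles."""
        test = self.model._subset(self.model.split.test_idx)
        return group_into_ensembles(test)

    def evaluate(
        self, ensembles: Sequence[ConformerEnsemble] | None = None
    ) -> EvalReport:
        """Benchmark report (MAE, Pearson r, misranking) on given or test data."""
        if ensembles is None:
            if self._test_report is None:
                self._test_report = evaluate_report(self.params, self.test_ensembles)
            return self._test_report
        return evaluate_report(self.params, list(ensembles))

    def test_mae(self) -> float:
        return evaluate_mae(self.params, self.model._subset(self.model.split.test_idx))

    def summary(self) -> str:
        """Human-readable fit summary."""
        m, t = self.model, self.train_result
        rep = self.evaluate()
        lines = [
            "Conformer energy model fit",
            "==========================",
            f"variant                  : {m.config.variant}",
            f"features / blocks / rbf  : {m.config.n_features} / "
            f"{m.config.n_blocks} / {m.config.n_rbf}",
            f"short-range cutoff (A)   : {m.config.cutoff}",
            f"structures (train/val/test): {len(m.split.train_idx)}/"
            f"{len(m.split.val_idx)}/{len(m.split.test_idx)}",
            f"steps trained            : {len(t.loss_history)}",
            f"final train loss         : {t.loss_history[-1]:.6g}",
            f"best val MAE (kcal/mol)  : {t.best_val_mae:.4f} @ step {t.best_step}",
            "",
            rep.summary(),
        ]
        return "\n".join(lines)

    # -- persistence & plots ----------------------------------------------
    def save(self, path) -> None:
        """Write a JSON checkpoint (config + weights with shape manifest)."""
        self.params.save(path)

    def plot_parity(self, ax=None):
        """Reference-vs-predicted relative-energy parity plot (test set)."""
        import matplotlib.pyplot as plt

        rep = self.evaluate()
        if ax is None:
            _, ax = plt.subplots()
        for _, dref, dhat in rep.relative_tables:
            ax.scatter(dref, dhat, s=8, alpha=0.5, color="tab:blue")
        lim = ax.get_xlim()
        ax.plot(lim, lim, "k--", lw=1)
        ax.set_xlabel(r"reference $\Delta E$ (kcal/mol)")
        ax.set_ylabel(r"predicted $\Delta E$ (kcal/mol)")
        ax.set_title(f"r = {rep.pearson_r:.3f}, MAE = {rep.mae:.2f} kcal/mol")
        return ax

    def plot_loss(self, ax=None):
        """Training-loss trace."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.semilogy(self.train_result.loss_history)
        ax.set_xlabel("step")
        ax.set_ylabel("loss")
        return ax
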