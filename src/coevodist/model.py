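"""High-level modelling API: DistanceMapModel.fit() -> DistanceMapResults.

The model object is built from a dataset of featurised targets (or raw
synthetic proteins / MSAs) plus an architecture configuration; fitting
runs the per-sample training loop and returns a results object that
carries the best weights, the training log, validation metrics, and a
``summary()`` table.  Prediction, evaluation and checkpointing hang off
the results object.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .metrics import DistanceMap, EvalSpec, MetricsReport, evaluate
from .msa import Alignment, PairFeatureTensor
from .nn import DistanceMapNet, ModelConfig, load_checkpoint, save_checkpoint
from .pipeline import TargetRecord, TrainConfig, featurize, featurize_protein, train
from .synthetic import SyntheticProtein


class DistanceMapModel:
    """A distance-map regression model bound to a training dataset.

    Parameters
    ----------
    targets
        Featurised targets with ground truth attached.
    config
        Architecture configuration; defaults to the desk-scale ``tiny``
        preset with the channel count inferred from the data.
    val_fraction
        Fraction of targets held out (deterministically under
        ``fit(seed)``) for validation and early stopping.
    """

    def __init__(
        self,
        targets: Sequence[TargetRecord],
        config: ModelConfig | None = None,
        val_fraction: float = 0.2,
    ):
        targets = list(targets)
        if not targets:
            raise ValueError("empty dataset")
        channels = {t.features.n_channels for t in targets}
        if len(channels) != 1:
            raise ConfigError(f"inconsistent channel counts across targets: {channels}")
        in_channels = channels.pop()
        if config is None:
            config = ModelConfig.tiny(in_channels)
        elif config.in_channels != in_channels:
            raise ConfigError(
                f"config expects {config.in_channels} channels, data has {in_channels}"
            )
        if not (0.0 <= val_fraction < 1.0):
            raise ValueError("val_fraction must be in [0, 1)")
        self.targets = targets
        self.config = config
        self.val_fraction = val_fraction

    @classmethod
    def from_proteins(
        cls,
        proteins: Sequence[SyntheticProtein],
        config: ModelConfig | None = None,
        **kwargs,
    ) -> "DistanceMapModel":
        return cls([featurize_protein(p) for p in proteins], config=config, **kwargs)

    def fit(self, train_config: TrainConfig | None = None) -> "DistanceMapResults":
        cfg = train_config or TrainConfig()
        rng = np.random.default_rng(cfg.seed & 0x7FFFFFFF)
        n_val = int(round(self.val_fraction * len(self.targets)))
        perm = rng.permutation(len(self.targets))
        val_idx = set(perm[:n_val].tolist())
        train_records = [t for i, t in enumerate(self.targets) if i not in val_idx]
        val_records = [t for i, t in enumerate(self.targets) if i in val_idx]

        net = DistanceMapNet(self.config, seed=cfg.seed & 0x7FFFFFFF)
        outcome = train(train_records, val_records, net, cfg)
        net.load_state_dict(outcome["best_state"])
        return DistanceMapResults(
            model=self,
            net=net,
            train_config=cfg,
            log=outcome["log"],
            best_val_loss=outcome["best_val_loss"],
            steps_run=outcome["steps_run"],
            train_ids=[t.id for t in train_records],
            val_ids=[t.id for t in val_records],
        )


@dataclasses.dataclass
class DistanceMapResults:
    """Fitted model state plus training diagnostics."""

    model: DistanceMapModel
    net: DistanceMapNet
    train_config: TrainConfig
    log: list[dict]
    best_val_loss: float | None
    steps_run: int
    train_ids: list[str]
    val_ids: list[str]

    # -- prediction --------------------------------------------------------

    def predict(
        self, target: TargetRecord | PairFeatureTensor | SyntheticProtein | Alignment
    ) -> DistanceMap:
        if isinstance(target, Alignment):
            target = featurize("query", target)
        if isinstance(target, SyntheticProtein):
            target = featurize_protein(target)
        features = target.features if isinstance(target, TargetRecord) else target
        if features.n_channels != self.net.cfg.in_channels:
            raise ConfigError(
                f"model expects {self.net.cfg.in_channels} input channels, "
                f"got {features.n_channels}"
            )
        return self.net.predict(features)

    def evaluate(
        self, targets: Sequence[TargetRecord], spec: EvalSpec | None = None
    ) -> list[tuple[str, MetricsReport]]:
        spec = spec or EvalSpec()
        return [(t.id, evaluate(self.predict(t), t.truth, spec)) for t in targets]

    # -- reporting ---------------------------------------------------------

    def log_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.log)

    def summary(self, eval_spec: EvalSpec | None = None) -> str:
        """Text summary: data, architecture, optimisation, validation metrics."""
        cfg, net = self.model.config, self.net
        lines = [
            "Distance map regression results",
            "=" * 47,
            f"{'Targets (train/val)':30s} {len(self.train_ids)}/{len(self.val_ids)}",
            f"{'Input channels':30s} {cfg.in_channels}",
            f"{'Encoder stages x channels':30s} {cfg.encoder_stages} x {cfg.base_channels}",
            f"{'Parameters':30s} {net.n_parameters()}",
            f"{'Steps run':30s} {self.steps_run}",
            f"{'Final train loss':30s} {self.log[-1]['train_loss']:.4f}",
        ]
        if self.best_val_loss is not None:
            lines.append(f"{'Best validation loss':30s} {self.best_val_loss:.4f}")
            val_maes = [e["val_pixel_mae"] for e in self.log if "val_pixel_mae" in e]
            if val_maes:
                lines.append(f"{'Last validation pixel-MAE (A)':30s} {val_maes[-1]:.4f}")
        val_targets = [t for t in self.model.targets if t.id in set(self.val_ids)]
        if val_targets:
            reports = self.evaluate(val_targets, eval_spec)
            prec = np.mean([r.precision["L/5"] for _, r in reports])
            lddt_v = np.mean([r.lddt for _, r in reports])
            lines += [
                f"{'Validation precision@L/5':30s} {prec:.4f}",
                f"{'Validation lDDT':30s} {lddt_v:.4f}",
            ]
        lines.append("=" * 47)
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        extra = {
            "train_config": dataclasses.asdict(self.train_config),
            "best_val_loss": self.best_val_loss,
            "steps_run": self.steps_run,
            "train_ids": self.train_ids,
            "val_ids": self.val_ids,
        }
        save_checkpoint(path, self.net, extra=extra)
        Path(path).with_suffix(".log.json").write_text(json.dumps(self.log))

    @staticmethod
    def load_net(path: str | Path) -> DistanceMapNet:
        net, _ = load_checkpoint(path)
        return net


__all__ = ["DistanceMapModel", "DistanceMapResults", "TargetRecord"]
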