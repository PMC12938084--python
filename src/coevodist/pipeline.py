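"""Training / evaluation orchestration.

Covers per-sample training with Adam and global-norm gradient clipping,
five-fold cross-validation with strict test-set isolation, prediction
output writers, the feature-space independence analysis (cosine
nearest-neighbour distances in a Z-scored embedding space), and
stratification of results by MSA depth (Neff/L bins).
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .errors import ConfigError, DimensionError, TrainingDivergedError
from .metrics import (
    DEFAULT_MIN_SEPARATION,
    LONG_RANGE_SEPARATION,
    DistanceMap,
    EvalSpec,
    MetricsReport,
    evaluate,
    pixel_mae,
)
from .msa import (
    Alignment,
    CouplingMatrix,
    PairFeatureTensor,
    ProfileFeatures,
    assemble_pair_features,
    covariant_contact_potential,
    sequence_weights,
)
from .nn import (
    Adam,
    DistanceMapNet,
    ModelConfig,
    Tensor,
    clip_global_norm,
    inv_log_cosh_loss_t,
    no_grad,
)
from .synthetic import SyntheticProtein

LENGTH_GATE = (50, 500)      # dataset assembly length filter


# ---------------------------------------------------------------------------
# featurisation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TargetRecord:
    """A featurised target: what the trainer and evaluator consume."""

    id: str
    features: PairFeatureTensor
    truth: DistanceMap | None
    profile: ProfileFeatures
    couplings: list[CouplingMatrix]
    neff: float

    @property
    def length(self) -> int:
        return self.features.length


def standardize_coupling(cm: CouplingMatrix) -> CouplingMatrix:
    """Z-score a coupling channel over its off-diagonal entries.

    Coupling scores are unbounded and typically much smaller in
    magnitude than the probability/entropy channels; standardisation
    puts them on a comparable footing in the input stack.
    """
    v = cm.values
    iu = np.triu_indices(v.shape[0], k=1)
    mu = v[iu].mean()
    sd = max(float(v[iu].std()), 1e-9)
    return CouplingMatrix((v - mu) / sd, cm.source)


def featurize(
    target_id: str,
    msa: Alignment,
    truth: DistanceMap | None = None,
    extra_couplings: Sequence[CouplingMatrix] = (),
    identity_threshold: float = 0.8,
    enforce_length_gate: bool = False,
    standardize_couplings: bool = True,
) -> TargetRecord:
    """MSA -> TargetRecord: weights, profile, internal MI coupling, tensor."""
    L = msa.length
    if enforce_length_gate and not (LENGTH_GATE[0] <= L <= LENGTH_GATE[1]):
        raise DimensionError(
            f"{target_id}: length {L} outside the {LENGTH_GATE} gate "
            "(pass enforce_length_gate=False to override)"
        )
    weights = sequence_weights(msa, thr=identity_threshold)
    profile = ProfileFeatures.from_alignment(msa, weights)
    couplings = [covariant_contact_potential(msa, weights), *extra_couplings]
    if standardize_couplings:
        couplings = [standardize_coupling(c) for c in couplings]
    features = assemble_pair_features(profile, couplings)
    return TargetRecord(
        id=target_id,
        features=features,
        truth=truth,
        profile=profile,
        couplings=couplings,
        neff=weights.neff,
    )


def featurize_protein(protein: SyntheticProtein, **kwargs) -> TargetRecord:
    return featurize(protein.id, protein.msa, truth=protein.truth, **kwargs)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TrainConfig:
    lr: float = 1e-3
    grad_clip_norm: float = 1.0
    max_steps: int = 500
    eval_interval: int = 25
    early_stop_patience: int = 20        # evaluations without improvement
    seed: int = 0
    loss_eps: float = 1e-8
    apply_kan_grid_updates: bool = True

    def __post_init__(self) -> None:
        if min(self.lr, self.grad_clip_norm, self.max_steps) <= 0:
            raise ValueError("lr, grad_clip_norm and max_steps must be positive")


def _validate(net: DistanceMapNet, records: Sequence[TargetRecord], eps: float):
    losses, maes = [], []
    with no_grad():
        for rec in records:
            x = Tensor(rec.features.tensor[None].astype(np.float64))
            out = net(x)
            pred = DistanceMap(out.data[0, 0], kind="predicted")
            losses.append(
                float(
                    inv_log_cosh_loss_t(out, rec.truth.values[None, None], eps).data
                )
            )
            maes.append(pixel_mae(pred, rec.truth))
    return float(np.mean(losses)), float(np.mean(maes))


def train(
    train_records: Sequence[TargetRecord],
    val_records: Sequence[TargetRecord],
    net: DistanceMapNet,
    cfg: TrainConfig,
) -> dict:
    """Per-sample (batch = 1) optimisation of the inverse-log-cosh loss.

    Returns a dict with the best state dict, the step log, and the best
    validation loss / pixel-MAE.  The monitoring MAE is element-wise
    over the whole map, deliberately distinct from top-K MAE.
    """
    if not train_records:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed & 0x7FFFFFFF)
    params = net.parameters()
    opt = Adam(params, lr=cfg.lr)
    log: list[dict] = []
    best_state = net.state_dict()
    best_val = math.inf
    evals_since_best = 0
    kan_interval = net.cfg.kan_grid_update_interval

    order: list[int] = []
    step = 0
    while step < cfg.max_steps:
        if not order:
            order = list(rng.permutation(len(train_records)))
        rec = train_records[order.pop()]
        x = Tensor(rec.features.tensor[None].astype(np.float64))
        out = net(x)
        loss = inv_log_cosh_loss_t(out, rec.truth.values[None, None], cfg.loss_eps)
        loss_val = float(loss.data)
        if not math.isfinite(loss_val):
            raise TrainingDivergedError(f"non-finite loss at step {step}")
        opt.zero_grad()
        loss.backward()
        clip_global_norm(params, cfg.grad_clip_norm)
        opt.step()
        step += 1

        if cfg.apply_kan_grid_updates and kan_interval > 0 and step % kan_interval == 0:
            net.update_kan_grid(x)

        entry = {"step": step, "train_loss": loss_val}
        if step % cfg.eval_interval == 0 or step == cfg.max_steps:
            if val_records:
                val_loss, val_mae = _validate(net, val_records, cfg.loss_eps)
                entry.update(val_loss=val_loss, val_pixel_mae=val_mae)
                if val_loss < best_val:
                    best_val = val_loss
                    best_state = net.state_dict()
                    evals_since_best = 0
                else:
                    evals_since_best += 1
            else:
                best_state = net.state_dict()
        log.append(entry)
        if val_records and evals_since_best >= cfg.early_stop_patience:
            break

    return {
        "best_state": best_state,
        "log": log,
        "best_val_loss": best_val if val_records else None,
        "steps_run": step,
    }


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class FoldPlan:
    assignments: dict[str, int]          # target id -> fold index
    k: int

    def __post_init__(self) -> None:
        folds = set(self.assignments.values())
        if folds - set(range(self.k)):
            raise ValueError("fold index out of range")

    def fold_ids(self, fold: int) -> list[str]:
        return sorted(tid for tid, f in self.assignments.items() if f == fold)

    def split(self, fold: int) -> tuple[list[str], list[str]]:
        """(train ids, validation ids) for one fold."""
        val = self.fold_ids(fold)
        train_ids = sorted(set(self.assignments) - set(val))
        return train_ids, val


def make_fold_plan(ids: Sequence[str], k: int = 5, seed: int = 0) -> FoldPlan:
    ids = list(ids)
    if len(ids) < k:
        raise ValueError(f"need at least k={k} targets, got {len(ids)}")
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    perm = rng.permutation(len(ids))
    assignments = {ids[int(p)]: i % k for i, p in enumerate(perm)}
    return FoldPlan(assignments=assignments, k=k)


def cross_validate(
    records: Sequence[TargetRecord],
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    k: int = 5,
    seed: int = 0,
    test_records: Sequence[TargetRecord] = (),
    spec: EvalSpec | None = None,
) -> dict:
    """k-fold cross-validation; the optional test set never enters any fold."""
    spec = spec or EvalSpec()
    by_id = {r.id: r for r in records}
    test_ids = {r.id for r in test_records}
    if test_ids & set(by_id):
        raise ConfigError("test targets overlap the cross-validation cohort")
    plan = make_fold_plan(list(by_id), k=k, seed=seed)

    fold_rows = []
    fold_reports: dict[int, list[tuple[str, MetricsReport]]] = {}
    for fold in range(k):
        train_ids, val_ids = plan.split(fold)
        assert not (set(train_ids) | set(val_ids)) & test_ids
        net = DistanceMapNet(model_cfg, seed=(seed * 1000 + fold) & 0x7FFFFFFF)
        result = train(
            [by_id[t] for t in train_ids],
            [by_id[t] for t in val_ids],
            net,
            dataclasses.replace(train_cfg, seed=(train_cfg.seed + fold) & 0x7FFFFFFF),
        )
        net.load_state_dict(result["best_state"])
        reports = []
        for tid in val_ids:
            rec = by_id[tid]
            pred = net.predict(rec.features)
            reports.append((tid, evaluate(pred, rec.truth, spec)))
        test_reports = [
            (rec.id, evaluate(net.predict(rec.features), rec.truth, spec))
            for rec in test_records
        ]
        fold_reports[fold] = reports
        row = {
            "fold": fold,
            "val_loss": result["best_val_loss"],
            "val_precision_L5": float(np.mean([r.precision["L/5"] for _, r in reports])),
            "val_mae_L5": float(np.mean([r.mae["L/5"] for _, r in reports])),
            "val_lddt": float(np.mean([r.lddt for _, r in reports])),
        }
        if test_reports:
            row["test_precision_L5"] = float(
                np.mean([r.precision["L/5"] for _, r in test_reports])
            )
        fold_rows.append(row)

    df = pd.DataFrame(fold_rows).set_index("fold")
    summary = pd.DataFrame({"mean": df.mean(), "std": df.std(ddof=1)})
    return {"plan": plan, "folds": df, "summary": summary, "reports": fold_reports}


# ---------------------------------------------------------------------------
# prediction output writers
# ---------------------------------------------------------------------------

def write_distance_outputs(out_dir: str | Path, target_id: str, dmap: DistanceMap) -> None:
    """Plain-text matrix, compressed array, and (i, j, d) records (1-based)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    header = "predicted Cb-Cb distances (A); row/col indices are 1-based in .rr output"
    np.savetxt(out_dir / f"{target_id}.dist.mat", dmap.values, fmt="%.4f", header=header)
    np.savez_compressed(out_dir / f"{target_id}.dist.npz", distances=dmap.values)
    L = dmap.length
    with open(out_dir / f"{target_id}.dist.rr", "w") as fh:
        fh.write(f"# {header}\n")
        for i in range(L):
            for j in range(i + 1, L):
                fh.write(f"{i + 1} {j + 1} {dmap.values[i, j]:.4f}\n")


def read_distance_matrix(path: str | Path) -> DistanceMap:
    return DistanceMap(np.loadtxt(path), kind="predicted")


# ---------------------------------------------------------------------------
# feature-space independence analysis
# ---------------------------------------------------------------------------

EMBED_QUANTILES = (0.1, 0.25, 0.5, 0.75, 0.9)


def _summary_stats(x: np.ndarray) -> np.ndarray:
    qs = np.quantile(x, EMBED_QUANTILES)
    return np.concatenate([[x.mean(), x.std()], qs])


def embed_target(record: TargetRecord) -> np.ndarray:
    """Fixed-length summary embedding of a target's feature distributions.

    Order: per-PSSM-symbol stats over positions (21 x 7), entropy stats
    (7), then upper-triangle stats of each coupling channel (7 each).
    """
    parts = [_summary_stats(record.profile.pssm[:, s]) for s in range(21)]
    parts.append(_summary_stats(record.profile.entropy))
    L = record.profile.length
    iu = np.triu_indices(L, k=1)
    for cm in record.couplings:
        parts.append(_summary_stats(cm.values[iu]))
    return np.concatenate(parts)


def independence_analysis(
    train_embeddings: np.ndarray, test_embeddings: np.ndarray
) -> dict:
    """Nearest-neighbour cosine distances, Z-scored on training statistics only."""
    train_embeddings = np.atleast_2d(np.asarray(train_embeddings, dtype=float))
    test_embeddings = np.atleast_2d(np.asarray(test_embeddings, dtype=float))
    if train_embeddings.shape[0] < 2:
        raise ValueError("need at least two training targets")
    mu = train_embeddings.mean(axis=0)
    sd = train_embeddings.std(axis=0)
    keep = sd > 1e-12
    n_dropped = int((~keep).sum())
    zt = (train_embeddings[:, keep] - mu[keep]) / sd[keep]
    zq = (test_embeddings[:, keep] - mu[keep]) / sd[keep]

    dtt_full = cdist(zt, zt, metric="cosine")
    np.fill_diagonal(dtt_full, np.inf)
    d_train_train = dtt_full.min(axis=1)
    d_test_train = cdist(zq, zt, metric="cosine").min(axis=1)
    return {
        "d_train_train": d_train_train,
        "d_test_train": d_test_train,
        "median_train_train": float(np.median(d_train_train)),
        "median_test_train": float(np.median(d_test_train)),
        "min_test_train": float(d_test_train.min()),
        "n_zero_variance_dropped": n_dropped,
    }


# ---------------------------------------------------------------------------
# Neff/L stratification
# ---------------------------------------------------------------------------

NEFF_BINS = ((0.0, 1.0), (1.0, 2.0), (2.0, 4.0), (4.0, np.inf))
NEFF_BIN_LABELS = ("<1", "1-2", "2-4", ">4")


def bin_by_neff(
    records: Sequence[TargetRecord],
    reports: dict[str, MetricsReport],
    long_range_lddt: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Mean ± std of precision@L/5 (and long-range lDDT) per Neff/L bin.

    Bin edges are left-closed: Neff/L = 1.0 falls in the "1-2" bin.
    Empty bins appear with count 0 and null metrics.
    """
    rows = []
    for (lo, hi), label in zip(NEFF_BINS, NEFF_BIN_LABELS):
        members = [r for r in records if lo <= r.neff / r.length < hi]
        prec = [reports[r.id].precision["L/5"] for r in members if r.id in reports]
        lddt_vals = (
            [long_range_lddt[r.id] for r in members if r.id in long_range_lddt]
            if long_range_lddt
            else []
        )
        rows.append(
            {
                "bin": label,
                "n_targets": len(members),
                "precision_L5_mean": float(np.mean(prec)) if prec else None,
                "precision_L5_std": float(np.std(prec, ddof=1)) if len(prec) > 1 else None,
                "lddt_lr_mean": float(np.mean(lddt_vals)) if lddt_vals else None,
                "lddt_lr_std": float(np.std(lddt_vals, ddof=1)) if len(lddt_vals) > 1 else None,
            }
        )
    return pd.DataFrame(rows).set_index("bin")


def long_range_spec() -> EvalSpec:
    """Seq-24 evaluation: min separation 24 for long-range stratification."""
    return EvalSpec(min_separation=LONG_RANGE_SEPARATION)


__all__ = [
    "TargetRecord",
    "TrainConfig",
    "FoldPlan",
    "featurize",
    "featurize_protein",
    "standardize_coupling",
    "train",
    "make_fold_plan",
    "cross_validate",
    "write_distance_outputs",
    "read_distance_matrix",
    "embed_target",
    "independence_analysis",
    "bin_by_neff",
    "long_range_spec",
    "LENGTH_GATE",
    "NEFF_BINS",
    "NEFF_BIN_LABELS",
    "DEFAULT_MIN_SEPARATION",
]
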