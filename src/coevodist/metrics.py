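"""Training loss and the distance-map evaluation suite.

The loss is an inverse-residual log-cosh: distances enter as 100/(d+eps)
so short (contact-forming) distances dominate the objective while the
log-cosh envelope keeps gradients bounded for large residuals.

Evaluation metrics: top-K contact precision and MAE at K in
{L/5, L/2, L}, Pearson correlation, lDDT over tolerances {0.5, 1, 2, 4} Å,
and MCC of the 8 Å contact classification.  All metrics score the upper
triangle at a configurable minimum sequence separation (6 by default;
24 for long-range, "Seq-24", evaluations).
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy import stats as _scipy_stats

from .errors import DimensionError, UndefinedCorrelationError

CONTACT_THRESHOLD = 8.0
LDDT_TOLERANCES = (0.5, 1.0, 2.0, 4.0)
DEFAULT_MIN_SEPARATION = 6
LONG_RANGE_SEPARATION = 24


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class DistanceMap:
    """L x L matrix of inter-residue distances in Å."""

    values: np.ndarray
    kind: str = "ground_truth"          # or "predicted"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise DimensionError(f"distance map must be square, got {v.shape}")
        if not np.isfinite(v).all():
            raise ValueError("distance map contains non-finite values")
        if self.kind == "ground_truth":
            if (v < 0).any():
                raise ValueError("ground-truth distances must be non-negative")
        elif self.kind == "predicted":
            if (v <= 0).any():
                raise ValueError("predicted distances must be strictly positive")
        else:
            raise ValueError(f"unknown distance map kind {self.kind!r}")
        object.__setattr__(self, "values", v)

    @property
    def length(self) -> int:
        return self.values.shape[0]

    @classmethod
    def from_coords(cls, coords: np.ndarray) -> "DistanceMap":
        """Ground-truth map from an (L, 3) coordinate array."""
        coords = np.asarray(coords, dtype=float)
        diff = coords[:, None, :] - coords[None, :, :]
        return cls(np.sqrt((diff**2).sum(axis=2)), kind="ground_truth")


@dataclasses.dataclass(frozen=True)
class ContactMap:
    values: np.ndarray                   # (L, L) bool
    threshold: float = CONTACT_THRESHOLD

    @property
    def length(self) -> int:
        return self.values.shape[0]


@dataclasses.dataclass(frozen=True)
class EvalSpec:
    top_fractions: tuple[float, ...] = (0.2, 0.5, 1.0)
    contact_threshold: float = CONTACT_THRESHOLD
    min_separation: int = DEFAULT_MIN_SEPARATION
    lddt_tolerances: tuple[float, ...] = LDDT_TOLERANCES

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.top_fractions):
            raise ValueError("top fractions must be positive")
        if list(self.lddt_tolerances) != sorted(self.lddt_tolerances):
            raise ValueError("lDDT tolerances must be sorted ascending")


@dataclasses.dataclass
class MetricsReport:
    precision: dict[str, float]          # keys "L/5", "L/2", "L"
    mae: dict[str, float]
    pearson_r: float
    lddt: float
    mcc: float
    n_pairs_scored: int
    min_separation: int
    contact_threshold: float
    truncated_topk: bool = False         # fewer eligible pairs than requested K

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def tsv_row(self, target_id: str = "") -> str:
        cells = [target_id]
        for k in ("L/5", "L/2", "L"):
            cells.append(f"{self.precision[k]:.4f}")
        for k in ("L/5", "L/2", "L"):
            cells.append(f"{self.mae[k]:.4f}")
        cells += [
            f"{self.pearson_r:.4f}",
            f"{self.lddt:.4f}",
            f"{self.mcc:.4f}",
            str(self.n_pairs_scored),
        ]
        return "\t".join(cells)

    TSV_HEADER = (
        "target\tprec_L5\tprec_L2\tprec_L\tmae_L5\tmae_L2\tmae_L\t"
        "pearson_r\tlddt\tmcc\tn_pairs"
    )


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def stable_log_cosh(u: np.ndarray) -> np.ndarray:
    """log(cosh(u)) evaluated as |u| + log1p(exp(-2|u|)) - log 2 (no overflow)."""
    a = np.abs(u)
    return a + np.log1p(np.exp(-2.0 * a)) - math.log(2.0)


def inv_log_cosh_loss(
    pred: DistanceMap | np.ndarray,
    truth: DistanceMap | np.ndarray,
    eps: float = 1e-8,
) -> float:
    """Mean over cells of log cosh(100/(pred+eps) - 100/(truth+eps))."""
    p = pred.values if isinstance(pred, DistanceMap) else np.asarray(pred, dtype=float)
    t = truth.values if isinstance(truth, DistanceMap) else np.asarray(truth, dtype=float)
    if p.shape != t.shape:
        raise DimensionError(f"shape mismatch {p.shape} vs {t.shape}")
    if eps <= 0:
        raise ValueError("eps must be positive")
    u = 100.0 / (p + eps) - 100.0 / (t + eps)
    return float(stable_log_cosh(u).mean())


# ---------------------------------------------------------------------------
# pair selection
# ---------------------------------------------------------------------------

def scored_pair_indices(L: int, min_separation: int) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle (i, j) index arrays with j - i >= max(min_separation, 1)."""
    k = max(int(min_separation), 1)
    iu = np.triu_indices(L, k=k)
    return iu


def _check_same_shape(pred: DistanceMap, truth: DistanceMap) -> int:
    if pred.length != truth.length:
        raise DimensionError(
            f"prediction length {pred.length} != truth length {truth.length}"
        )
    return pred.length


def _topk_selection(
    pred: DistanceMap, fraction: float, spec: EvalSpec
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Indices of the top-K pairs by ascending predicted distance.

    K = ceil(fraction * L).  Ties broken by (i, j) lexicographic order.
    If fewer eligible pairs exist, all are used and a warning is issued.
    """
    L = pred.length
    ii, jj = scored_pair_indices(L, spec.min_separation)
    if ii.size == 0:
        raise DimensionError("no eligible pairs at this separation")
    K = int(math.ceil(fraction * L))
    truncated = False
    if K > ii.size:
        warnings.warn(
            f"only {ii.size} eligible pairs for requested top-{K}; scoring all",
            stacklevel=3,
        )
        K = ii.size
        truncated = True
    d = pred.values[ii, jj]
    order = np.lexsort((jj, ii, d))[:K]
    return ii[order], jj[order], truncated


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def contacts_from_distances(
    dmap: DistanceMap, threshold: float = CONTACT_THRESHOLD
) -> ContactMap:
    """Binary contacts: distance strictly below threshold, diagonal excluded."""
    if threshold <= 0:
        raise ValueError("contact threshold must be positive")
    values = dmap.values < threshold
    np.fill_diagonal(values, False)
    return ContactMap(values=values, threshold=threshold)


def topk_precision(
    pred: DistanceMap, truth: DistanceMap, fraction: float, spec: EvalSpec | None = None
) -> float:
    spec = spec or EvalSpec()
    _check_same_shape(pred, truth)
    ii, jj, _ = _topk_selection(pred, fraction, spec)
    hits = truth.values[ii, jj] < spec.contact_threshold
    return float(hits.mean())


def topk_mae(
    pred: DistanceMap, truth: DistanceMap, fraction: float, spec: EvalSpec | None = None
) -> float:
    spec = spec or EvalSpec()
    _check_same_shape(pred, truth)
    ii, jj, _ = _topk_selection(pred, fraction, spec)
    return float(np.abs(pred.values[ii, jj] - truth.values[ii, jj]).mean())


def pixel_mae(pred: DistanceMap, truth: DistanceMap) -> float:
    """Element-wise MAE over the full L x L map (training-monitoring metric)."""
    _check_same_shape(pred, truth)
    return float(np.abs(pred.values - truth.values).mean())


def pearson_r(
    pred: DistanceMap, truth: DistanceMap, spec: EvalSpec | None = None
) -> float:
    spec = spec or EvalSpec()
    L = _check_same_shape(pred, truth)
    ii, jj = scored_pair_indices(L, spec.min_separation)
    p, t = pred.values[ii, jj], truth.values[ii, jj]
    if p.size < 2 or np.std(p) == 0 or np.std(t) == 0:
        raise UndefinedCorrelationError(
            "Pearson correlation undefined: fewer than two pairs or zero variance"
        )
    return float(_scipy_stats.pearsonr(p, t).statistic)


def lddt(pred: DistanceMap, truth: DistanceMap, spec: EvalSpec | None = None) -> float:
    """Mean over tolerances of the fraction of scored pairs within tolerance."""
    spec = spec or EvalSpec()
    L = _check_same_shape(pred, truth)
    ii, jj = scored_pair_indices(L, spec.min_separation)
    if ii.size == 0:
        raise DimensionError("no eligible pairs at this separation")
    err = np.abs(pred.values[ii, jj] - truth.values[ii, jj])
    fracs = [(err < t).mean() for t in spec.lddt_tolerances]
    return float(np.mean(fracs))


def mcc_from_counts(tp: int, tn: int, fp: int, fn: int) -> float:
    """Matthews correlation coefficient; zero denominator maps to 0 by convention."""
    denom = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / denom


def mcc(
    pred_contacts: ContactMap,
    true_contacts: ContactMap,
    min_separation: int = DEFAULT_MIN_SEPARATION,
) -> float:
    if pred_contacts.length != true_contacts.length:
        raise DimensionError("contact maps differ in size")
    ii, jj = scored_pair_indices(pred_contacts.length, min_separation)
    p = pred_contacts.values[ii, jj]
    t = true_contacts.values[ii, jj]
    tp = int(np.sum(p & t))
    tn = int(np.sum(~p & ~t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    return mcc_from_counts(tp, tn, fp, fn)


_FRACTION_LABELS = {0.2: "L/5", 0.5: "L/2", 1.0: "L"}


def evaluate(
    pred: DistanceMap, truth: DistanceMap, spec: EvalSpec | None = None
) -> MetricsReport:
    """Full metric report on one target (single pass over the scored pairs)."""
    spec = spec or EvalSpec()
    L = _check_same_shape(pred, truth)
    ii, jj = scored_pair_indices(L, spec.min_separation)
    if ii.size == 0:
        raise DimensionError("no eligible pairs at this separation")

    precision: dict[str, float] = {}
    mae: dict[str, float] = {}
    truncated = False
    for frac in spec.top_fractions:
        label = _FRACTION_LABELS.get(frac, f"L*{frac:g}")
        si, sj, trunc = _topk_selection(pred, frac, spec)
        truncated = truncated or trunc
        precision[label] = float(
            (truth.values[si, sj] < spec.contact_threshold).mean()
        )
        mae[label] = float(np.abs(pred.values[si, sj] - truth.values[si, sj]).mean())

    pc = contacts_from_distances(pred, spec.contact_threshold)
    tc = contacts_from_distances(truth, spec.contact_threshold)
    return MetricsReport(
        precision=precision,
        mae=mae,
        pearson_r=pearson_r(pred, truth, spec),
        lddt=lddt(pred, truth, spec),
        mcc=mcc(pc, tc, spec.min_separation),
        n_pairs_scored=int(ii.size),
        min_separation=spec.min_separation,
        contact_threshold=spec.contact_threshold,
        truncated_topk=truncated,
    )


# ---------------------------------------------------------------------------
# ground truth from PDB
# ---------------------------------------------------------------------------

def distance_map_from_pdb(path: str | Path, chain_id: str | None = None) -> DistanceMap:
    """Cβ–Cβ ground-truth distances from a PDB file (Cα fallback for glycine).

    Residues are taken in order from the first model; ``chain_id`` selects
    a chain (default: first chain encountered).
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("target", str(path))
    model = next(structure.get_models())
    chains = list(model.get_chains())
    if chain_id is not None:
        chains = [c for c in chains if c.id == chain_id]
        if not chains:
            raise DimensionError(f"chain {chain_id!r} not found in {path}")
    chain = chains[0]
    coords = []
    for res in chain.get_residues():
        if res.id[0].strip():          # skip heteroatoms / waters
            continue
        atom = None
        if "CB" in res:
            atom = res["CB"]
        elif "CA" in res:              # glycine has no Cβ
            atom = res["CA"]
        if atom is not None:
            coords.append(atom.coord)
    if len(coords) < 2:
        raise DimensionError(f"fewer than two usable residues in {path}")
    return DistanceMap.from_coords(np.asarray(coords, dtype=float))


# ---------------------------------------------------------------------------
# report aggregation
# ---------------------------------------------------------------------------

def write_reports_tsv(path: str | Path, reports: Iterable[tuple[str, MetricsReport]]) -> None:
    lines = [MetricsReport.TSV_HEADER]
    lines += [rep.tsv_row(tid) for tid, rep in reports]
    Path(path).write_text("\n".join(lines) + "\n")


__all__ = [
    "DistanceMap",
    "ContactMap",
    "EvalSpec",
    "MetricsReport",
    "inv_log_cosh_loss",
    "stable_log_cosh",
    "contacts_from_distances",
    "topk_precision",
    "topk_mae",
    "pixel_mae",
    "pearson_r",
    "lddt",
    "mcc",
    "mcc_from_counts",
    "evaluate",
    "scored_pair_indices",
    "distance_map_from_pdb",
    "write_reports_tsv",
    "CONTACT_THRESHOLD",
    "LDDT_TOLERANCES",
    "DEFAULT_MIN_SEPARATION",
    "LONG_RANGE_SEPARATION",
]
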