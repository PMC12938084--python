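"""MSA parsing and MSA-derived feature extraction.

Everything the network consumes is derived from a multiple sequence
alignment: a sequence-weighted PSSM (amino-acid occurrence probabilities
per column), per-column Shannon entropy, and residue-pair coupling
statistics.  Couplings can be read from external plain-text predictors
(CCMpred square matrices, FreeContact triplet records) or computed
in-repo as sequence-weighted mutual information with average product
correction (APC), which serves as the covariant-frequency contact
potential channel.

Sequence weighting follows the standard effective-sequence-number (Neff)
convention: each row is weighted by the inverse count of rows within an
identity threshold ``thr`` of it (the row itself included), and
Neff is the sum of the weights.  Identity is the fraction of matching
symbols over columns where the query is non-gap; gap matching gap counts
as a match.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO

from .alphabet import (
    AA20,
    GAP,
    GAP_CODE,
    N_PSSM_SYMBOLS,
    UNKNOWN_CODE,
    decode_sequence,
    encode_sequence,
)
from .errors import DimensionError, EmptyInputError, MSAFormatError

COUPLING_SOURCES = ("ccmpred", "freecontact", "internal_mi", "contact_potential")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class Alignment:
    """An MSA: equal-length aligned rows, first row is the ungapped query."""

    ids: list[str]
    rows: list[str]
    _encoded: np.ndarray | None = dataclasses.field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.rows:
            raise EmptyInputError("alignment has no sequences")
        L = len(self.rows[0])
        if L < 1:
            raise MSAFormatError("query row is empty")
        for rid, row in zip(self.ids, self.rows):
            if len(row) != L:
                raise MSAFormatError(
                    f"row {rid!r} has length {len(row)}, expected {L}"
                )
        if GAP in self.rows[0]:
            raise MSAFormatError("query (first row) must not contain gaps")

    @property
    def depth(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def query(self) -> str:
        return self.rows[0]

    def encoded(self) -> np.ndarray:
        """Integer-coded alignment of shape (depth, length)."""
        if self._encoded is None:
            self._encoded = np.stack([encode_sequence(r) for r in self.rows])
        return self._encoded


@dataclasses.dataclass(frozen=True)
class SequenceWeights:
    weights: np.ndarray          # (M,), each in (0, 1]
    neff: float
    identity_threshold: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if not ((w > 0).all() and (w <= 1 + 1e-12).all()):
            raise ValueError("sequence weights must lie in (0, 1]")


@dataclasses.dataclass(frozen=True)
class ProfileFeatures:
    """Per-residue profile: PSSM over 20 AAs + gap, and column entropy (bits)."""

    pssm: np.ndarray       # (L, 21)
    entropy: np.ndarray    # (L,)

    @property
    def length(self) -> int:
        return self.pssm.shape[0]

    @classmethod
    def from_alignment(
        cls,
        aln: Alignment,
        weights: SequenceWeights | None = None,
        pseudocount: float = 1.0,
    ) -> "ProfileFeatures":
        if weights is None:
            weights = sequence_weights(aln)
        return cls(
            pssm=compute_pssm(aln, weights, pseudocount=pseudocount),
            entropy=column_entropy(aln, weights),
        )


@dataclasses.dataclass(frozen=True)
class CouplingMatrix:
    values: np.ndarray     # (L, L)
    source: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise DimensionError(f"coupling matrix must be square, got {v.shape}")
        if not np.isfinite(v).all():
            raise ValueError("coupling matrix contains non-finite entries")
        if self.source not in COUPLING_SOURCES:
            raise ValueError(f"unknown coupling source {self.source!r}")

    @property
    def length(self) -> int:
        return self.values.shape[0]

    def symmetrized(self) -> "CouplingMatrix":
        return CouplingMatrix((self.values + self.values.T) / 2.0, self.source)


@dataclasses.dataclass(frozen=True)
class PairFeatureTensor:
    """C x L x L input stack: tiled per-residue profiles plus 2D couplings."""

    tensor: np.ndarray             # (C, L, L) float32
    channel_names: list[str]

    def __post_init__(self) -> None:
        if self.tensor.ndim != 3 or self.tensor.shape[1] != self.tensor.shape[2]:
            raise DimensionError(f"expected (C, L, L), got {self.tensor.shape}")
        if len(self.channel_names) != self.tensor.shape[0]:
            raise DimensionError("channel_names length must equal channel count")
        if not np.isfinite(self.tensor).all():
            raise ValueError("pair feature tensor contains non-finite entries")

    @property
    def n_channels(self) -> int:
        return self.tensor.shape[0]

    @property
    def length(self) -> int:
        return self.tensor.shape[1]


# ---------------------------------------------------------------------------
# alignment I/O
# ---------------------------------------------------------------------------

def _strip_a3m_insertions(seq: str) -> str:
    # a3m marks insertion states as lowercase letters (and '.'), which are
    # relative to the query and must be dropped to restore column register
    return "".join(c for c in seq if not (c.islower() or c == "."))


def read_msa(path: str | Path, format: str | None = None) -> Alignment:
    """Read a FASTA or A3M alignment.

    ``format`` may be ``"fasta"``, ``"a3m"`` or ``None`` (infer from the
    file suffix, defaulting to FASTA).
    """
    path = Path(path)
    if format is None:
        format = "a3m" if path.suffix.lower() == ".a3m" else "fasta"
    if format not in ("fasta", "a3m"):
        raise ValueError(f"unsupported alignment format {format!r}")

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyInputError(f"no sequences found in {path}")

    ids = [rec.id for rec in records]
    rows = [str(rec.seq) for rec in records]
    if format == "a3m":
        rows = [_strip_a3m_insertions(r) for r in rows]
    rows = [r.upper() for r in rows]

    L = len(rows[0])
    for rid, row in zip(ids, rows):
        if len(row) != L:
            raise MSAFormatError(
                f"row {rid!r} in {path.name} has length {len(row)}, expected {L}"
            )
    try:
        aln = Alignment(ids=ids, rows=rows)
        aln.encoded()
    except ValueError as exc:
        raise MSAFormatError(f"{path.name}: {exc}") from exc
    return aln


def write_msa(path: str | Path, aln: Alignment) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(aln.ids, aln.rows):
            fh.write(f">{rid}\n{row}\n")


# ---------------------------------------------------------------------------
# sequence weighting / Neff
# ---------------------------------------------------------------------------

def sequence_weights(
    aln: Alignment, thr: float = 0.8, chunk_size: int = 256
) -> SequenceWeights:
    """Inverse-neighbour-count sequence weights and Neff at identity cutoff ``thr``.

    weight_m = 1 / |{n : identity(m, n) >= thr}| with m in its own
    neighbour set, and Neff = sum of weights.  Identity is computed over
    columns where the query is non-gap.
    """
    if not (0.0 < thr <= 1.0):
        raise ValueError(f"identity threshold must be in (0, 1], got {thr}")
    enc = aln.encoded()
    mask = enc[0] != GAP_CODE
    cols = enc[:, mask]
    n_cols = cols.shape[1]
    if n_cols == 0:
        raise MSAFormatError("query has no non-gap columns")
    M = cols.shape[0]
    counts = np.zeros(M, dtype=np.int64)
    for start in range(0, M, chunk_size):
        block = cols[start : start + chunk_size]
        ident = (block[:, None, :] == cols[None, :, :]).sum(axis=2) / n_cols
        counts[start : start + chunk_size] = (ident >= thr - 1e-12).sum(axis=1)
    weights = 1.0 / counts
    return SequenceWeights(
        weights=weights, neff=float(weights.sum()), identity_threshold=thr
    )


# ---------------------------------------------------------------------------
# profile features
# ---------------------------------------------------------------------------

def _weighted_counts(aln: Alignment, w: np.ndarray) -> np.ndarray:
    """Weighted symbol counts per column over the 21-symbol profile alphabet.

    'X' rows contribute fractionally (w/20) to every amino-acid bin, so
    total counts per column always sum to sum(w).
    """
    enc = aln.encoded()
    L = aln.length
    counts = np.empty((L, N_PSSM_SYMBOLS), dtype=float)
    for s in range(N_PSSM_SYMBOLS):
        counts[:, s] = w @ (enc == s)
    x_mass = w @ (enc == UNKNOWN_CODE)
    counts[:, :20] += x_mass[:, None] / 20.0
    return counts


def compute_pssm(
    aln: Alignment, weights: SequenceWeights, pseudocount: float = 1.0
) -> np.ndarray:
    """Sequence-weighted amino-acid probability profile with Laplace smoothing.

    p(c, a) = (pc + sum_m w_m [row_m[c] = a]) / (21 pc + sum_m w_m).
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    w = np.asarray(weights.weights, dtype=float)
    counts = _weighted_counts(aln, w)
    denom = N_PSSM_SYMBOLS * pseudocount + w.sum()
    return (pseudocount + counts) / denom


def column_entropy(aln: Alignment, weights: SequenceWeights) -> np.ndarray:
    """Shannon entropy (bits) of the weighted column distribution, no pseudocount."""
    w = np.asarray(weights.weights, dtype=float)
    counts = _weighted_counts(aln, w)
    p = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log2(p), 0.0)
    return np.maximum(-terms.sum(axis=1), 0.0)


# ---------------------------------------------------------------------------
# coupling statistics
# ---------------------------------------------------------------------------

def _mi_matrix(aln: Alignment, w: np.ndarray, block: int = 16) -> np.ndarray:
    """Weighted mutual information (bits) between all column pairs.

    Joint frequencies are taken over rows where both columns are non-gap;
    'X' is treated as its own 21st symbol.  Computed via a one-hot Gram
    matrix so the per-pair gap exclusion falls out of the algebra.
    """
    enc = aln.encoded()
    M, L = enc.shape
    n_sym = 21  # 20 AAs + X; gap excluded (all-zero one-hot row)
    codes = np.where(enc == UNKNOWN_CODE, 20, enc)   # X -> symbol 20
    onehot = np.zeros((M, L, n_sym), dtype=np.float64)
    nongap = enc != GAP_CODE
    m_idx, l_idx = np.nonzero(nongap)
    onehot[m_idx, l_idx, codes[m_idx, l_idx]] = 1.0
    flat = onehot.reshape(M, L * n_sym)
    gram = (flat * w[:, None]).T @ flat          # (L*n, L*n)
    J = gram.reshape(L, n_sym, L, n_sym)

    mi = np.zeros((L, L), dtype=float)
    for i0 in range(0, L, block):
        i1 = min(i0 + block, L)
        Jb = J[i0:i1]                            # (b, n, L, n)
        tot = Jb.sum(axis=(1, 3))                # (b, L)
        safe_tot = np.where(tot > 0, tot, 1.0)
        P = Jb / safe_tot[:, None, :, None]
        pa = P.sum(axis=3)                       # (b, n, L)
        pb = P.sum(axis=1)                       # (b, L, n)
        denom = pa[:, :, :, None] * pb[:, None, :, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(P > 0, P * np.log2(P / np.where(denom > 0, denom, 1.0)), 0.0)
        mi[i0:i1] = np.where(tot > 0, term.sum(axis=(1, 3)), 0.0)
    np.fill_diagonal(mi, 0.0)
    return np.maximum((mi + mi.T) / 2.0, 0.0)


def apc_correct(mi: np.ndarray) -> np.ndarray:
    """Average product correction: MI_APC(i,j) = MI(i,j) - MI(i,.) MI(.,j) / MI(.,.).

    Row/column/overall means exclude the diagonal.  Diagonal of the
    result is zero.
    """
    L = mi.shape[0]
    if L < 2:
        return np.zeros_like(mi)
    off = mi.copy()
    np.fill_diagonal(off, 0.0)
    row_mean = off.sum(axis=1) / (L - 1)
    overall = off.sum() / (L * (L - 1))
    if overall <= 0:
        corrected = off
    else:
        corrected = off - np.outer(row_mean, row_mean) / overall
    np.fill_diagonal(corrected, 0.0)
    return (corrected + corrected.T) / 2.0


def covariant_contact_potential(
    aln: Alignment, weights: SequenceWeights | None = None
) -> CouplingMatrix:
    """Sequence-weighted mutual information with APC, the in-repo coupling channel."""
    if aln.length < 2:
        raise DimensionError("coupling statistics need at least two columns")
    if weights is None:
        weights = sequence_weights(aln)
    mi = _mi_matrix(aln, np.asarray(weights.weights, dtype=float))
    return CouplingMatrix(apc_correct(mi), source="internal_mi")


def mutual_information(
    aln: Alignment, weights: SequenceWeights | None = None
) -> np.ndarray:
    """Weighted column-pair mutual information (bits), without APC."""
    if weights is None:
        weights = sequence_weights(aln)
    return _mi_matrix(aln, np.asarray(weights.weights, dtype=float))


# ---------------------------------------------------------------------------
# external coupling files
# ---------------------------------------------------------------------------

def read_coupling_matrix(path: str | Path, L: int, source: str) -> CouplingMatrix:
    """Read an external coupling file.

    ``ccmpred``: whitespace-delimited L x L matrix.  ``freecontact``:
    one record per line with 1-based residue indices in the first two
    columns and the score in the last; missing pairs are zero and the
    matrix is symmetrized by mirroring.
    """
    path = Path(path)
    if source == "freecontact":
        values = np.zeros((L, L), dtype=float)
        n_records = 0
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                tokens = line.split()
                if not tokens or tokens[0].startswith("#"):
                    continue
                try:
                    i, j = int(tokens[0]), int(tokens[1])
                    score = float(tokens[-1])
                except (ValueError, IndexError) as exc:
                    raise MSAFormatError(
                        f"{path.name}:{lineno}: cannot parse triplet record"
                    ) from exc
                if not (1 <= i <= L and 1 <= j <= L):
                    raise DimensionError(
                        f"{path.name}:{lineno}: index ({i},{j}) outside 1..{L}"
                    )
                values[i - 1, j - 1] = score
                values[j - 1, i - 1] = score
                n_records += 1
        if n_records == 0:
            raise EmptyInputError(f"no coupling records in {path}")
        return CouplingMatrix(values, source=source)

    try:
        values = np.loadtxt(path, dtype=float)
    except ValueError as exc:
        raise MSAFormatError(f"{path.name}: cannot parse matrix file") from exc
    values = np.atleast_2d(values)
    if values.shape != (L, L):
        raise DimensionError(
            f"{path.name}: expected {L}x{L} matrix, got {values.shape}"
        )
    return CouplingMatrix(values, source=source).symmetrized()


# ---------------------------------------------------------------------------
# feature assembly
# ---------------------------------------------------------------------------

PER_RESIDUE_FEATURE_COUNT = N_PSSM_SYMBOLS + 1   # pssm row ++ entropy = 22


def assemble_pair_features(
    profile: ProfileFeatures, couplings: Sequence[CouplingMatrix] = ()
) -> PairFeatureTensor:
    """Tile per-residue profiles into pair channels and stack 2D couplings.

    Cell (i, j) carries [f_i ; f_j] where f is the 22-dim per-residue
    vector (21 PSSM probabilities + entropy), followed by one channel
    per coupling matrix.  C = 2*22 + len(couplings).
    """
    L = profile.length
    for cm in couplings:
        if cm.length != L:
            raise DimensionError(
                f"coupling matrix of size {cm.length} does not match profile length {L}"
            )
    f = np.hstack([profile.pssm, profile.entropy[:, None]])    # (L, 22)
    n_f = f.shape[1]
    fi = np.broadcast_to(f.T[:, :, None], (n_f, L, L))
    fj = np.broadcast_to(f.T[:, None, :], (n_f, L, L))

    per_res_names = [f"pssm_{a}" for a in AA20] + ["pssm_gap", "entropy"]
    names = [f"res_i/{n}" for n in per_res_names] + [f"res_j/{n}" for n in per_res_names]
    layers = [fi, fj]
    seen: dict[str, int] = {}
    for cm in couplings:
        k = seen.get(cm.source, 0)
        seen[cm.source] = k + 1
        suffix = "" if k == 0 else f"_{k}"
        names.append(f"pair/{cm.source}{suffix}")
        layers.append(cm.values[None, :, :])
    tensor = np.concatenate(layers, axis=0).astype(np.float32)
    return PairFeatureTensor(tensor=tensor, channel_names=names)


def save_pair_features(path: str | Path, features: PairFeatureTensor) -> None:
    """Persist a feature tensor as compressed arrays plus a JSON channel manifest."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), tensor=features.tensor)
    manifest = {"channels": features.channel_names, "length": features.length}
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def load_pair_features(path: str | Path) -> PairFeatureTensor:
    path = Path(path)
    tensor = np.load(path.with_suffix(".npz"))["tensor"]
    manifest = json.loads(path.with_suffix(".json").read_text())
    return PairFeatureTensor(tensor=tensor, channel_names=list(manifest["channels"]))


__all__ = [
    "Alignment",
    "SequenceWeights",
    "ProfileFeatures",
    "CouplingMatrix",
    "PairFeatureTensor",
    "read_msa",
    "write_msa",
    "sequence_weights",
    "compute_pssm",
    "column_entropy",
    "covariant_contact_potential",
    "mutual_information",
    "apc_correct",
    "read_coupling_matrix",
    "assemble_pair_features",
    "save_pair_features",
    "load_pair_features",
    "decode_sequence",
]
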