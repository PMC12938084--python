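"""Self-contained synthetic proteins: 3D chains, distance maps, pseudo-MSAs.

The generator emulates exactly the statistical structure the feature
stack assumes, with none of the physics: a compact self-avoiding
Cβ-proxy chain built from helix-like and extended segments gives a
ground-truth distance map with realistic contact density; a pseudo-MSA
evolved from a random ancestor carries conserved columns, variable
columns, and compensatory paired mutations at contacting positions so
that coevolution statistics (MI/APC) are informative about contacts.

Everything is deterministic under (params, seed).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from .alphabet import AA20
from .errors import GenerationError
from .metrics import DistanceMap, distance_map_from_pdb
from .msa import Alignment, read_msa, write_msa

MIN_BOND = 3.0          # Å, allowed consecutive-residue spacing lower bound
MAX_BOND = 4.5          # Å, upper bound
CLASH = 3.0             # Å, minimum non-adjacent approach
CONTACT_CUTOFF = 8.0
CONTACT_MIN_SEP = 6


@dataclasses.dataclass(frozen=True)
class GeneratorParams:
    length_range: tuple[int, int] = (50, 120)
    n_sequences: int = 100
    mutation_rate: float = 0.15
    coupling_strength: float = 3.0
    contact_fraction: float = 0.06      # nominal target density (diagnostic)
    conserved_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if not (10 <= lo <= hi):
            raise ValueError("length_range must satisfy 10 <= lo <= hi")
        if not (0.0 < self.mutation_rate < 1.0):
            raise ValueError("mutation_rate must be in (0, 1)")
        if self.coupling_strength < 0:
            raise ValueError("coupling_strength must be >= 0")
        if self.n_sequences < 2:
            raise ValueError("need at least 2 sequences")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["length_range"] = list(d["length_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorParams":
        d = dict(d)
        d["length_range"] = tuple(d["length_range"])
        return cls(**d)


@dataclasses.dataclass
class SyntheticProtein:
    id: str
    coords: np.ndarray              # (L, 3) Å
    sequence: str
    msa: Alignment
    truth: DistanceMap
    seed: int
    params: GeneratorParams

    @property
    def length(self) -> int:
        return self.coords.shape[0]


# ---------------------------------------------------------------------------
# structure generation
# ---------------------------------------------------------------------------

def _helix_segment(n_points: int) -> np.ndarray:
    """Idealised helix: radius 2.3 Å, rise 1.5 Å, 100° turn per residue."""
    t = np.arange(n_points, dtype=float)
    ang = np.deg2rad(100.0) * t
    pts = np.stack([2.3 * np.cos(ang), 2.3 * np.sin(ang), 1.5 * t], axis=1)
    return pts - pts[0]


def _extended_segment(n_points: int) -> np.ndarray:
    t = np.arange(n_points, dtype=float)
    return np.stack([np.zeros_like(t), np.zeros_like(t), 3.8 * t], axis=1)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    return Rotation.from_quat(q / np.linalg.norm(q)).as_matrix()


def _grow_chain(L: int, rng: np.random.Generator, radius: float) -> np.ndarray | None:
    """One growth attempt: segments joined by random-rotation linkers."""
    pts: list[np.ndarray] = [np.zeros(3)]
    helix = bool(rng.random() < 0.5)
    while len(pts) < L:
        n_new = int(rng.integers(7, 13) if helix else rng.integers(4, 9))
        n_new = min(n_new, L - len(pts))
        local = _helix_segment(n_new + 1) if helix else _extended_segment(n_new + 1)
        existing = np.asarray(pts)
        centroid = existing.mean(axis=0)
        anchor = pts[-1]

        best: np.ndarray | None = None
        best_end = np.inf
        for _ in range(24):
            R = _random_rotation(rng)
            cand = anchor + (local[1:] - local[0]) @ R.T
            # clash check against all existing points except the anchor bond
            d = np.linalg.norm(cand[:, None, :] - existing[None, :, :], axis=2)
            d[0, -1] = np.inf          # first new point is bonded to the anchor
            if d.min() < CLASH:
                continue
            end_dist = float(np.linalg.norm(cand[-1] - centroid))
            if end_dist <= radius:
                best = cand
                break
            if end_dist < best_end:
                best, best_end = cand, end_dist
        if best is None:
            return None
        pts.extend(best)
        helix = not helix
    return np.asarray(pts[:L])


def generate_structure(L: int, seed: int, max_retries: int = 80) -> np.ndarray:
    """Compact self-avoiding Cβ-proxy chain of length L; deterministic per seed."""
    if L < 10:
        raise ValueError("need L >= 10")
    radius = 3.4 * L ** (1.0 / 3.0)
    for attempt in range(max_retries):
        rng = np.random.default_rng([seed & 0x7FFFFFFF, attempt])
        coords = _grow_chain(L, rng, radius)
        if coords is None:
            continue
        steps = np.linalg.norm(np.diff(coords, axis=0), axis=1)
        if steps.min() < MIN_BOND or steps.max() > MAX_BOND:
            continue
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        sep = np.abs(np.subtract.outer(np.arange(L), np.arange(L)))
        if d[sep >= 2].min() < CLASH:
            continue
        return coords
    raise GenerationError(f"structure generation failed for L={L}, seed={seed}")


def contact_pairs(coords: np.ndarray, cutoff: float = CONTACT_CUTOFF,
                  min_sep: int = CONTACT_MIN_SEP) -> np.ndarray:
    """(n_pairs, 2) array of i<j contacts at |i-j| >= min_sep."""
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
    L = coords.shape[0]
    ii, jj = np.triu_indices(L, k=min_sep)
    keep = d[ii, jj] < cutoff
    return np.stack([ii[keep], jj[keep]], axis=1)


def contact_density(coords: np.ndarray) -> float:
    L = coords.shape[0]
    ii, jj = np.triu_indices(L, k=CONTACT_MIN_SEP)
    if ii.size == 0:
        return 0.0
    return contact_pairs(coords).shape[0] / ii.size


# ---------------------------------------------------------------------------
# pseudo-MSA simulation
# ---------------------------------------------------------------------------

def simulate_msa(
    coords: np.ndarray,
    L: int,
    params: GeneratorParams,
    seed: int,
) -> Alignment:
    """Evolve a coevolution-bearing pseudo-MSA from a random ancestor.

    Conserved columns are planted at ``conserved_fraction`` of positions;
    each contact pair (not touching a conserved column) is assigned a
    two-state covarying letter repertoire, applied per descendant with
    probability min(1, coupling_strength * mutation_rate).
    """
    if coords.shape[0] != L:
        raise ValueError("coords length mismatch")
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    M = params.n_sequences

    conserved = np.zeros(L, dtype=bool)
    n_cons = max(1, int(round(params.conserved_fraction * L)))
    conserved[rng.choice(L, size=n_cons, replace=False)] = True

    pairs = contact_pairs(coords)
    pairs = pairs[~(conserved[pairs[:, 0]] | conserved[pairs[:, 1]])]
    # two-state covarying repertoire per pair: (a1,b1) or (a2,b2)
    states = rng.integers(0, 20, size=(pairs.shape[0], 2, 2))

    ancestor = rng.integers(0, 20, size=L)
    for p, (i, j) in enumerate(pairs):
        ancestor[i], ancestor[j] = states[p, 0]

    p_pair = min(1.0, params.coupling_strength * params.mutation_rate)
    rows = [ancestor]
    for _ in range(M - 1):
        seq = ancestor.copy()
        mutate = (rng.random(L) < params.mutation_rate) & ~conserved
        seq[mutate] = rng.integers(0, 20, size=int(mutate.sum()))
        if pairs.shape[0] and p_pair > 0:
            apply = rng.random(pairs.shape[0]) < p_pair
            chosen = rng.integers(0, 2, size=pairs.shape[0])
            for p in np.nonzero(apply)[0]:
                i, j = pairs[p]
                seq[i], seq[j] = states[p, chosen[p]]
        rows.append(seq)

    row_strings = ["".join(AA20[c] for c in r) for r in rows]
    ids = ["query"] + [f"seq_{k:04d}" for k in range(1, M)]
    return Alignment(ids=ids, rows=row_strings)


# ---------------------------------------------------------------------------
# whole targets and on-disk fixture trees
# ---------------------------------------------------------------------------

def generate_protein(params: GeneratorParams, index: int = 0,
                     protein_id: str | None = None) -> SyntheticProtein:
    """Deterministic target #index under (params.seed, index)."""
    ss = np.random.SeedSequence([params.seed & 0x7FFFFFFF, index])
    s_len, s_struct, s_msa = [int(s) & 0x7FFFFFFF for s in ss.generate_state(3)]
    lo, hi = params.length_range
    L = int(np.random.default_rng(s_len).integers(lo, hi + 1))
    coords = generate_structure(L, seed=s_struct)
    msa = simulate_msa(coords, L, params, seed=s_msa)
    return SyntheticProtein(
        id=protein_id or f"synth_{index:03d}",
        coords=coords,
        sequence=msa.query,
        msa=msa,
        truth=DistanceMap.from_coords(coords),
        seed=s_struct,
        params=params,
    )


def write_minimal_pdb(path: str | Path, coords: np.ndarray, sequence: str) -> None:
    """Minimal single-chain PDB: one Cβ-proxy atom per residue (Cα for glycine)."""
    from Bio.SeqUtils import seq3

    lines = []
    for i, (aa, xyz) in enumerate(zip(sequence, coords), start=1):
        name = "CA" if aa == "G" else "CB"
        resname = seq3(aa).upper()
        x, y, z = (float(v) for v in xyz)
        lines.append(
            f"ATOM  {i:5d} {name:^4s} {resname:<3s} A{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}           C"
        )
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def make_dataset(
    n: int, params: GeneratorParams, out_dir: str | Path | None = None
) -> list[SyntheticProtein]:
    """Generate ``n`` targets; optionally write the fixture tree.

    Layout: ``<out_dir>/targets/<id>/{msa.fasta, truth.mat, model.pdb,
    manifest.json}`` plus a top-level ``manifest.json``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    proteins = [generate_protein(params, index=i) for i in range(n)]
    if out_dir is None:
        return proteins

    out_dir = Path(out_dir)
    entries = []
    for prot in proteins:
        tdir = out_dir / "targets" / prot.id
        tdir.mkdir(parents=True, exist_ok=True)
        write_msa(tdir / "msa.fasta", prot.msa)
        np.savetxt(tdir / "truth.mat", prot.truth.values, fmt="%.6f")
        write_minimal_pdb(tdir / "model.pdb", prot.coords, prot.sequence)
        manifest = {
            "id": prot.id,
            "length": prot.length,
            "seed": prot.seed,
            "sequence": prot.sequence,
            "params": prot.params.to_dict(),
        }
        (tdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        entries.append(manifest)
    (out_dir / "manifest.json").write_text(
        json.dumps({"n_targets": n, "targets": entries}, indent=2)
    )
    return proteins


def load_dataset(out_dir: str | Path) -> list[SyntheticProtein]:
    """Reload a fixture tree through the public readers."""
    out_dir = Path(out_dir)
    manifest = json.loads((out_dir / "manifest.json").read_text())
    proteins = []
    for entry in manifest["targets"]:
        tdir = out_dir / "targets" / entry["id"]
        msa = read_msa(tdir / "msa.fasta")
        truth = DistanceMap(np.loadtxt(tdir / "truth.mat"), kind="ground_truth")
        pdb_map = distance_map_from_pdb(tdir / "model.pdb")
        if pdb_map.length != truth.length:
            raise GenerationError(f"fixture {entry['id']}: PDB/matrix length mismatch")
        proteins.append(
            SyntheticProtein(
                id=entry["id"],
                coords=np.full((truth.length, 3), np.nan),   # coords live in the PDB
                sequence=entry["sequence"],
                msa=msa,
                truth=truth,
                seed=entry["seed"],
                params=GeneratorParams.from_dict(entry["params"]),
            )
        )
    return proteins


__all__ = [
    "GeneratorParams",
    "SyntheticProtein",
    "generate_structure",
    "simulate_msa",
    "generate_protein",
    "make_dataset",
    "load_dataset",
    "write_minimal_pdb",
    "contact_pairs",
    "contact_density",
]
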