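"""Amino-acid alphabet and integer encoding shared across the package.

Residues are encoded as integers: the 20 canonical amino acids in the
order of ``AA20``, then the alignment gap ``-`` (code 20), then the
unknown/ambiguous symbol ``X`` (code 21).  Non-canonical letters that
occur in real alignments (B, Z, J, U, O) are mapped to ``X`` on input.
"""

from __future__ import annotations

import numpy as np

AA20 = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"

GAP_CODE = 20
UNKNOWN_CODE = 21
N_CODES = 22          # 20 AAs + gap + unknown
N_PSSM_SYMBOLS = 21   # 20 AAs + gap (profile alphabet)

_ENCODE = np.full(128, -1, dtype=np.int8)
for _i, _a in enumerate(AA20):
    _ENCODE[ord(_a)] = _i
_ENCODE[ord(GAP)] = GAP_CODE
_ENCODE[ord(UNKNOWN)] = UNKNOWN_CODE
for _a in "BZJUO":    # ambiguous / rare letters -> unknown
    _ENCODE[ord(_a)] = UNKNOWN_CODE


def encode_sequence(seq: str) -> np.ndarray:
    """Encode an aligned sequence to integer codes; raises on foreign symbols."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = _ENCODE[arr]
    if (codes < 0).any():
        bad = chr(arr[int(np.argmax(codes < 0))])
        raise ValueError(f"unrecognised alignment symbol {bad!r}")
    return codes.astype(np.int8)


def decode_sequence(codes: np.ndarray) -> str:
    symbols = AA20 + GAP + UNKNOWN
    return "".join(symbols[int(c)] for c in codes)
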