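"""Smith-Waterman scoring of sequences against a position-specific matrix.

The inner Gotoh recursion is JIT-compiled with numba; the first call in a
process pays the compilation cost (~1 s).
"""

from __future__ import annotations

import numpy as np
from numba import njit

_NT_CODE = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _NT_CODE[ord(_c)] = _i
    _NT_CODE[ord(_c.lower())] = _i

_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_CODE = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate(_AA):
    _AA_CODE[ord(_c)] = _i
    _AA_CODE[ord(_c.lower())] = _i

#: score applied at positions whose symbol is outside the profile alphabet
_UNKNOWN_SCORE = -4.0


def encode(seq: str, alphabet: str = "nucleotide") -> np.ndarray:
    table = _NT_CODE if alphabet == "nucleotide" else _AA_CODE
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(fastmath=False)
def _sw_best(col_scores, seq, gap_open, gap_extend):  # pragma: no cover - jit
    n_cols = col_scores.shape[0]
    best = 0.0
    H = np.zeros(n_cols + 1)
    E = np.full(n_cols + 1, -1e30)
    for i in range(seq.size):
        code = seq[i]
        diag = 0.0
        F = -1e30
        for j in range(1, n_cols + 1):
            e = H[j] - gap_open
            if E[j] - gap_extend > e:
                e = E[j] - gap_extend
            E[j] = e
            f = H[j - 1] - gap_open
            if F - gap_extend > f:
                f = F - gap_extend
            F = f
            if code >= 0:
                h = diag + col_scores[j - 1, code]
            else:
                h = diag + _UNKNOWN_SCORE
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            diag = H[j]
            H[j] = h
            if h > best:
                best = h
    return best


def score_sequence(
    col_scores: np.ndarray, seq: str, gap_open: float, gap_extend: float,
    alphabet: str = "nucleotide",
) -> float:
    """Best local-alignment score of ``seq`` against the profile matrix."""
    codes = encode(seq, alphabet)
    return float(_sw_best(col_scores, codes, gap_open, gap_extend))


def score_many(
    col_scores: np.ndarray, seqs, gap_open: float, gap_extend: float,
    alphabet: str = "nucleotide",
) -> np.ndarray:
    return np.array(
        [score_sequence(col_scores, s, gap_open, gap_extend, alphabet) for s in seqs]
    )
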