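"""Global (Needleman-Wunsch) alignment primitives shared by clustering and
de novo/database peptide comparison.

Scoring is the simple scheme match +1 / mismatch -1 / linear gap -1. Because
several co-optimal alignments can exist, the number of "identical aligned
positions" is ambiguous under score alone; here the dynamic programme
maximises the pair (score, identities) lexicographically, which is
deterministic and symmetric in its two arguments.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MATCH = 1
MISMATCH = -1
GAP = -1


@njit(cache=False)
def _nw_kernel(a: np.ndarray, b: np.ndarray):  # pragma: no cover - jitted
    n = a.shape[0]
    m = b.shape[0]
    # rolling rows of (score, identities), lexicographic maximisation
    prev_s = np.empty(m + 1, dtype=np.int64)
    prev_i = np.empty(m + 1, dtype=np.int64)
    cur_s = np.empty(m + 1, dtype=np.int64)
    cur_i = np.empty(m + 1, dtype=np.int64)
    for j in range(m + 1):
        prev_s[j] = -j
        prev_i[j] = 0
    for i in range(1, n + 1):
        cur_s[0] = -i
        cur_i[0] = 0
        ai = a[i - 1]
        for j in range(1, m + 1):
            if ai == b[j - 1]:
                s = prev_s[j - 1] + 1
                d = prev_i[j - 1] + 1
            else:
                s = prev_s[j - 1] - 1
                d = prev_i[j - 1]
            # gap in b (consume a[i-1])
            s_up = prev_s[j] - 1
            if s_up > s or (s_up == s and prev_i[j] > d):
                s = s_up
                d = prev_i[j]
            # gap in a (consume b[j-1])
            s_left = cur_s[j - 1] - 1
            if s_left > s or (s_left == s and cur_i[j - 1] > d):
                s = s_left
                d = cur_i[j - 1]
            cur_s[j] = s
            cur_i[j] = d
        prev_s, cur_s = cur_s, prev_s
        prev_i, cur_i = cur_i, prev_i
    return prev_s[m], prev_i[m]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def nw_align(seq_a: str, seq_b: str) -> tuple[int, int]:
    """Return (raw NW score, identical aligned positions).

    The identity count is the maximum attainable over all score-optimal
    global alignments, so the result is symmetric and reproducible.
    """
    if not seq_a or not seq_b:
        raise ValueError("alignment requires two non-empty sequences")
    s, ident = _nw_kernel(_encode(seq_a), _encode(seq_b))
    return int(s), int(ident)


def global_identity(seq_a: str, seq_b: str) -> float:
    """Fraction of identical aligned positions over the shorter length.

    The shorter-sequence denominator mirrors the convention of greedy
    sequence-clustering tools, so a fragment scores 1.0 against its parent.
    """
    _, ident = nw_align(seq_a, seq_b)
    return ident / min(len(seq_a), len(seq_b))


def scaled_similarity(seq_a: str, seq_b: str) -> float:
    """NW raw score scaled to [0, 100]; 100 iff the sequences are identical.

    scaled = 100 * max(0, raw) / max(len_a, len_b). Any substitution or
    length difference strictly lowers the raw score below the longer
    length, so 100 is attained exactly at identity.
    """
    score, _ = nw_align(seq_a, seq_b)
    return 100.0 * max(0, score) / max(len(seq_a), len(seq_b))
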