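"""Independent reference implementations used only to check the package.

Everything here is deliberately written from the definitions, in plain
Python (full-matrix dynamic programming, math.comb enumeration, step-up
loops), sharing no code with the implementation under test.
"""

from __future__ import annotations

import math


def nw_full_matrix(a: str, b: str) -> tuple[int, int]:
    """Quadratic-space NW with match +1 / mismatch -1 / gap -1.

    Cell values are (score, identities) pairs maximised lexicographically;
    returns the bottom-right cell.
    """
    n, m = len(a), len(b)
    D = [[(0, 0)] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        D[i][0] = (-i, 0)
    for j in range(1, m + 1):
        D[0][j] = (-j, 0)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            match = a[i - 1] == b[j - 1]
            ds, dd = D[i - 1][j - 1]
            diag = (ds + (1 if match else -1), dd + (1 if match else 0))
            us, ud = D[i - 1][j]
            up = (us - 1, ud)
            ls, ld = D[i][j - 1]
            left = (ls - 1, ld)
            D[i][j] = max(diag, up, left)
    return D[n][m]


def identity_oracle(a: str, b: str) -> float:
    _, ident = nw_full_matrix(a, b)
    return ident / min(len(a), len(b))


def similarity_oracle(a: str, b: str) -> float:
    score, _ = nw_full_matrix(a, b)
    return 100.0 * max(0, score) / max(len(a), len(b))


def bh_adjust(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values (independent loop)."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, pvals[i] * m / rank_from_top)
        adj[i] = running
    return adj


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), by direct enumeration."""
    denom = math.comb(N, n)
    total = 0
    for j in range(k, min(K, n) + 1):
        if n - j <= N - K:
            total += math.comb(K, j) * math.comb(N - K, n - j)
    return total / denom


def digest_oracle(sequence: str, missed_cleavages_max: int,
                  min_len: int = 6, max_len: int = 50) -> set[str]:
    """Enumerate every substring and keep the valid tryptic peptides.

    A substring qualifies if both ends sit on cleavage boundaries (or the
    termini), it skips at most ``missed_cleavages_max`` internal cleavage
    sites, and its length is inside the detectability window.
    """
    L = len(sequence)
    def is_site(pos: int) -> bool:  # boundary between pos-1 and pos
        return (0 < pos < L and sequence[pos - 1] in "KR"
                and sequence[pos] != "P")
    boundaries = [0] + [p for p in range(1, L) if is_site(p)] + [L]
    out = set()
    for start in boundaries:
        for end in boundaries:
            if end <= start:
                continue
            internal = sum(1 for p in boundaries if start < p < end)
            if internal <= missed_cleavages_max and \
                    min_len <= end - start <= max_len:
                out.add(sequence[start:end])
    return out
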