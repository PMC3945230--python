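"""Independent brute-force oracles used only by the tests.

These deliberately share no code with the package: plain-Python
dynamic programming for global (Gotoh) and local (Smith–Waterman)
affine-gap alignment scores, direct window recounts, and a direct
binomial tail sum.  Gap runs of length L cost open + L * extend,
matching the package's convention.
"""

from __future__ import annotations

import math

NEG = float("-inf")


def naive_global_score(s1: str, s2: str, match: int, mismatch: int,
                       gap_open: int, gap_extend: int) -> float:
    """Affine-gap Needleman–Wunsch–Gotoh optimum, score only."""
    n, m = len(s1), len(s2)
    oe = gap_open + gap_extend
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in s2
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in s1
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = -(gap_open + i * gap_extend)
    for j in range(1, m + 1):
        Iy[0][j] = -(gap_open + j * gap_extend)
    for i in range(1, n + 1):
        ci = s1[i - 1]
        for j in range(1, m + 1):
            s = match if (ci == s2[j - 1] and ci != "N") else mismatch
            M[i][j] = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]) + s
            Ix[i][j] = max(M[i - 1][j] - oe, Ix[i - 1][j] - gap_extend,
                           Iy[i - 1][j] - oe)
            Iy[i][j] = max(M[i][j - 1] - oe, Iy[i][j - 1] - gap_extend,
                           Ix[i][j - 1] - oe)
    return max(M[n][m], Ix[n][m], Iy[n][m])


def naive_local_score(s1: str, s2: str, match: int, mismatch: int,
                      gap_open: int, gap_extend: int) -> float:
    """Affine-gap Smith–Waterman optimum, score only."""
    n, m = len(s1), len(s2)
    oe = gap_open + gap_extend
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        ci = s1[i - 1]
        for j in range(1, m + 1):
            s = match if (ci == s2[j - 1] and ci != "N") else mismatch
            E[i][j] = max(H[i][j - 1] - oe, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - oe, F[i - 1][j] - gap_extend)
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


def recount_windows(row1: str, row2: str, window_len: int) -> list[float]:
    """Direct per-window match recount over alignment columns."""
    out = []
    n = len(row1)
    for start in range(0, n - window_len + 1, window_len):
        matches = 0
        for a, b in zip(row1[start:start + window_len], row2[start:start + window_len]):
            if a == b and a != "-" and a != "N":
                matches += 1
        out.append(matches / window_len)
    return out


def binomial_tail(n: int, p: float, k_min: int) -> float:
    """P[Bin(n, p) >= k_min] by direct term summation."""
    total = 0.0
    for k in range(k_min, n + 1):
        total += math.comb(n, k) * p ** k * (1 - p) ** (n - k)
    return total


def perfect_runs(row1: str, row2: str) -> list[int]:
    """Mismatch-free run lengths by direct enumeration."""
    runs, cur = [], 0
    for a, b in zip(row1, row2):
        if a == b and a != "-" and a != "N":
            cur += 1
        else:
            if cur:
                runs.append(cur)
            cur = 0
    if cur:
        runs.append(cur)
    return runs
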