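"""Independent brute-force reference implementations.

These deliberately avoid the package's code paths (and the library
calls behind them) so agreement is a real cross-check: plain Python
loops, O(n^2) pair counting, direct probability arithmetic.
"""

from __future__ import annotations

import math
from collections import Counter


def brute_count_kmers(sequences: list[str], k: int) -> Counter:
    """Position-by-position window scan; windows containing N skipped."""
    counts: Counter = Counter()
    for seq in sequences:
        for i in range(len(seq) - k + 1):
            window = seq[i : i + k]
            if "N" in window:
                continue
            counts[window] += 1
    return counts


_WC = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
_WOBBLE = {("G", "U"), ("U", "G")}


def brute_seed_match(motif: str, seed: str, allow_wobble: bool = True):
    """Enumerate the six duplex positions against the pairing table.

    Returns (pairings, wobble_count) or None.
    """
    assert len(motif) == len(seed)
    n = len(motif)
    pairings = []
    wobbles = 0
    for i in range(n):
        pair = (motif[i], seed[n - 1 - i])
        if pair in _WC:
            pairings.append("WC")
        elif allow_wobble and pair in _WOBBLE:
            pairings.append("wobble")
            wobbles += 1
        else:
            return None
    return pairings, wobbles


def brute_tau_b(x: list[float], y: list[float]) -> float:
    """Exhaustive O(n^2) pair classification with tie terms."""
    n = len(x)
    concordant = discordant = 0
    ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                ties_x += 1
                ties_y += 1
            elif dx == 0:
                ties_x += 1
            elif dy == 0:
                ties_y += 1
            elif dx * dy > 0:
                concordant += 1
            else:
                discordant += 1
    n0 = n * (n - 1) // 2
    denom = math.sqrt((n0 - ties_x) * (n0 - ties_y))
    return (concordant - discordant) / denom


def brute_relative_score(matrix_cols: list[dict[str, float]], window: str) -> float:
    """Direct (S - Smin)/(Smax - Smin) on already-normalised columns."""
    s = sum(math.log(col[b]) for col, b in zip(matrix_cols, window))
    s_min = sum(math.log(min(col.values())) for col in matrix_cols)
    s_max = sum(math.log(max(col.values())) for col in matrix_cols)
    if s_max == s_min:
        return 1.0
    return (s - s_min) / (s_max - s_min)


def brute_scan(sequence: str, matrix_cols: list[dict[str, float]], threshold: float):
    """All (1-based start, score) hits of a PWM over one sequence."""
    L = len(matrix_cols)
    hits = []
    for i in range(len(sequence) - L + 1):
        window = sequence[i : i + L]
        if any(b not in "ACGU" for b in window):
            continue
        score = brute_relative_score(matrix_cols, window)
        if score >= threshold:
            hits.append((i + 1, score))
    return hits
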