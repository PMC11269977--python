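"""Independent brute-force oracles used to check the fast implementations.

Everything here is deliberately naive: plain Python loops and direct
arithmetic (no log-space tricks, no vectorization), kept free of any code
path shared with the package internals.
"""

from __future__ import annotations

import math

import numpy as np

BASES = "ACGT"
IDX = {b: i for i, b in enumerate(BASES)}


def naive_site_weight(matrix, site: str) -> float:
    w = 1.0
    for i, b in enumerate(site):
        w *= matrix[i][IDX[b]]
    return w


def naive_read_weight(matrix, read: str) -> float:
    lw = len(matrix)
    return sum(
        naive_site_weight(matrix, read[j : j + lw]) for j in range(len(read) - lw + 1)
    )


def naive_total_weight(matrix, e0: float, read: str) -> float:
    lw = len(matrix)
    n_win = len(read) - lw + 1
    unspec = 0.0 if e0 == -math.inf else n_win * math.exp(e0)
    return naive_read_weight(matrix, read) + unspec


def naive_log_likelihood(seqs, counts, priors, matrix, e0: float) -> float:
    weights = [naive_total_weight(matrix, e0, s) for s in seqs]
    z = sum(f * w for f, w in zip(priors, weights))
    total = 0.0
    for n, f, w in zip(counts, priors, weights):
        total += n * math.log(f * w / z)
    return total


def naive_selection_probs(seqs, priors, matrix, e0: float):
    weights = [naive_total_weight(matrix, e0, s) for s in seqs]
    num = [f * w for f, w in zip(priors, weights)]
    z = sum(num)
    return [v / z for v in num]


def naive_update_pwm(seqs, counts, matrix, e0: float):
    """Double-loop responsibility accumulation, un-normalized."""
    lw = len(matrix)
    accum = [[0.0] * 4 for _ in range(lw)]
    for seq, n in zip(seqs, counts):
        denom = naive_total_weight(matrix, e0, seq)
        if denom == 0.0:
            continue
        for j in range(len(seq) - lw + 1):
            site = seq[j : j + lw]
            w = n * naive_site_weight(matrix, site) / denom
            for i, b in enumerate(site):
                accum[i][IDX[b]] += w
    return np.array(accum)


def grid_optimize_e0(seqs, counts, priors, matrix, lo=-30.0, hi=0.0, step=1e-3) -> float:
    """Exhaustive grid scan plus one level of local refinement.

    Specific read weights are precomputed once (they do not depend on E0);
    the scan itself is direct arithmetic.
    """
    lw = len(matrix)
    spec = np.array([naive_read_weight(matrix, s) for s in seqs])
    n_win = np.array([len(s) - lw + 1 for s in seqs], dtype=float)
    f = np.asarray(priors, dtype=float)
    n = np.asarray(counts, dtype=float)

    def ll(e0_grid):
        # direct formula, broadcast over the grid: W = spec + n_win * e^{E0}
        w = spec[None, :] + n_win[None, :] * np.exp(e0_grid)[:, None]
        z = (f[None, :] * w).sum(axis=1)
        return (n[None, :] * np.log(f[None, :] * w / z[:, None])).sum(axis=1)

    grid = np.arange(lo, hi + step / 2, step)
    best = int(np.argmax(ll(grid)))
    a = grid[max(0, best - 1)]
    b = grid[min(len(grid) - 1, best + 1)]
    fine = np.linspace(a, b, 201)
    return float(fine[int(np.argmax(ll(fine)))])


def dp_levenshtein(a: str, b: str) -> int:
    """Textbook quadratic dynamic program."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
        prev = cur
    return prev[len(b)]
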