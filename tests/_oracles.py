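"""Independent brute-force reference implementations used only by tests.

Everything here is written as directly as possible (double loops, explicit
enumeration, Floyd-Warshall) and stays independent of the package code paths
it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt


def sampen_bruteforce(y, m, r_abs):
    """Sample entropy by explicit O(N^2) pair counting, Chebyshev distance."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    nt = n - m
    a = b = 0
    for i in range(nt - 1):
        for j in range(i + 1, nt):
            if max(abs(y[i + k] - y[j + k]) for k in range(m)) <= r_abs:
                b += 1
                if abs(y[i + m] - y[j + m]) <= r_abs:
                    a += 1
    if a == b:
        return 0.0 if b > 0 else float("nan")
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def pe_bruteforce(y, m):
    """Permutation entropy (bits) by explicit motif counting.

    Ties are broken by order of appearance, matching a stable argsort.
    """
    y = list(map(float, y))
    counts: dict[tuple, int] = {}
    n_windows = len(y) - m + 1
    for start in range(n_windows):
        w = y[start : start + m]
        motif = tuple(sorted(range(m), key=lambda k: (w[k], k)))
        counts[motif] = counts.get(motif, 0) + 1
    h = 0.0
    for c in counts.values():
        p = c / n_windows
        h -= p * math.log2(p)
    return h


def wpli_bruteforce(terms):
    """wPLI of a flat collection of complex terms by explicit summation."""
    num = 0.0
    den = 0.0
    count = 0
    for z in np.ravel(np.asarray(terms)):
        im = z.imag
        num += im
        den += abs(im)
        count += 1
    if count == 0 or den == 0:
        return 0.0
    return abs(num / count) / (den / count)


def hilbert_pair_wpli(x1, x2, f_lo, f_hi, fs):
    """Oracle wPLI of two raw signals via analytic-signal cross terms.

    Band-pass both signals, take Hilbert analytic signals, and apply the
    wPLI ratio to the per-sample cross terms z1 * conj(z2).  Estimation
    route (time-domain analytic signal) is independent of the package's
    epoch-FFT route.
    """
    sos = butter(4, [f_lo, f_hi], btype="bandpass", fs=fs, output="sos")
    z1 = hilbert(sosfiltfilt(sos, np.asarray(x1, dtype=float)))
    z2 = hilbert(sosfiltfilt(sos, np.asarray(x2, dtype=float)))
    cross = z1 * np.conj(z2)
    im = cross.imag
    den = np.abs(im).mean()
    return 0.0 if den == 0 else abs(im.mean()) / den


# ---------------------------------------------------------------------------
# graph oracles: adjacency is a square 0/1 numpy array


def floyd_warshall(adj):
    n = adj.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    d[adj.astype(bool)] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def global_eff_oracle(adj):
    n = adj.shape[0]
    if n < 2:
        return 0.0
    d = floyd_warshall(adj)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def local_eff_oracle(adj):
    n = adj.shape[0]
    if n == 0:
        return 0.0
    total = 0.0
    for i in range(n):
        nb = [j for j in range(n) if adj[i, j]]
        if len(nb) >= 2:
            sub = adj[np.ix_(nb, nb)]
            total += global_eff_oracle(sub)
    return total / n


def nodal_eff_oracle(adj, i):
    n = adj.shape[0]
    if n < 2:
        return 0.0
    d = floyd_warshall(adj)
    return sum(
        1.0 / d[i, j] for j in range(n) if j != i and np.isfinite(d[i, j])
    ) / (n - 1)


def clustering_oracle(adj):
    """Per-node clustering by explicit triangle enumeration; returns (c_i, mean)."""
    n = adj.shape[0]
    c = np.zeros(n)
    for i in range(n):
        nb = [j for j in range(n) if adj[i, j]]
        k = len(nb)
        if k < 2:
            continue
        triangles = sum(
            1 for u, v in itertools.combinations(nb, 2) if adj[u, v]
        )
        c[i] = 2.0 * triangles / (k * (k - 1))
    return c, c.mean() if n else 0.0


def path_length_oracle(adj):
    """Characteristic path length over connected ordered pairs; nan if none."""
    n = adj.shape[0]
    d = floyd_warshall(adj)
    vals = [d[i, j] for i in range(n) for j in range(n)
            if i != j and np.isfinite(d[i, j])]
    return float(np.mean(vals)) if vals else float("nan")


def bh_fdr_oracle(pvalues):
    """Step-up BH applied literally from its definition."""
    p = list(map(float, pvalues))
    n = len(p)
    order = sorted(range(n), key=lambda i: p[i])
    adj = [None] * n
    for rank_pos in range(n):
        i = order[rank_pos]
        candidates = [
            n * p[order[j]] / (j + 1) for j in range(rank_pos, n)
        ]
        adj[i] = min(1.0, min(candidates))
    return np.array(adj)
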