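"""Independent brute-force oracles used by the unit and acceptance suites.

Each oracle is written from the mathematical definition, without reuse
of the package's implementation path.
"""

from __future__ import annotations

import functools

import numpy as np


def brute_force_peaks(t, a, min_rr, prominence_frac):
    """Exhaustive scan for strict local maxima under the same
    prominence and separation constraints as the beat detector.

    Prominence of a peak is its height above the higher of the two base
    minima, where each base minimum is taken between the peak and the
    nearest strictly higher sample (or the signal edge) on that side.
    Separation is enforced greedily in decreasing height order, ties to
    the earlier sample.
    """
    a = np.asarray(a, dtype=float)
    t = np.asarray(t, dtype=float)
    n = a.size
    candidates = [i for i in range(1, n - 1) if a[i - 1] < a[i] > a[i + 1]]
    threshold = prominence_frac * float(np.std(a))

    def prominence(i):
        left = a[i]
        j = i - 1
        while j >= 0 and a[j] <= a[i]:
            left = min(left, a[j])
            j -= 1
        right = a[i]
        j = i + 1
        while j < n and a[j] <= a[i]:
            right = min(right, a[j])
            j += 1
        return a[i] - max(left, right)

    candidates = [i for i in candidates if prominence(i) >= threshold]
    kept: list[int] = []
    for i in sorted(candidates, key=lambda i: (-a[i], i)):
        if all(abs(t[i] - t[j]) >= min_rr for j in kept):
            kept.append(i)
    return sorted(kept)


def optimal_monotone_matching(pen, ecg, max_offset):
    """Recursive enumeration of the best monotone matching.

    Returns ``(n_pairs, total_abs_offset)`` maximizing the pair count,
    breaking ties by minimal total absolute offset.
    """
    pen = tuple(float(v) for v in pen)
    ecg = tuple(float(v) for v in ecg)

    @functools.lru_cache(maxsize=None)
    def go(i, j):
        if i == len(pen) or j == len(ecg):
            return (0, 0.0)
        best = max(go(i + 1, j), go(i, j + 1), key=lambda v: (v[0], -v[1]))
        d = abs(pen[i] - ecg[j])
        if d <= max_offset:
            c, cost = go(i + 1, j + 1)
            cand = (c + 1, cost + d)
            if (cand[0], -cand[1]) > (best[0], -best[1]):
                best = cand
        return best

    return go(0, 0)


def permutation_welch_p(x, y, n_perm, rng):
    """Two-sided permutation p-value for the Welch statistic.

    Permutes group labels ``n_perm`` times and counts permuted |t| at
    least as large as the observed |t|.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])

    def welch_t(a, b, axis=None):
        ma, mb = a.mean(axis=axis), b.mean(axis=axis)
        va, vb = a.var(ddof=1, axis=axis), b.var(ddof=1, axis=axis)
        return (ma - mb) / np.sqrt(va / nx + vb / ny)

    t_obs = abs(welch_t(x, y))
    order = np.argsort(rng.random((n_perm, nx + ny)), axis=1)
    perm = pooled[order]
    t_perm = welch_t(perm[:, :nx], perm[:, nx:], axis=1)
    return float(np.mean(np.abs(t_perm) >= t_obs))
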