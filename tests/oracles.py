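"""Independent brute-force oracles used by the test suite.

These are deliberately naive O(n^2)-or-worse reference computations written
against the documented definitions only, and are kept free of any code from
the package's own implementation paths.
"""

from __future__ import annotations

import numpy as np


def brute_force_repeats(seq, unit_min, unit_max, min_copies):
    """Enumerate maximal primitive perfect tandem repeats by testing every
    (start, unit_size) pair directly.

    Returns a set of (start, end, unit, copies) tuples.
    """
    seq = seq.upper()
    n = len(seq)
    out = set()
    for u in range(unit_min, unit_max + 1):
        for start in range(0, n - u * min_copies + 1):
            unit = seq[start : start + u]
            if "N" in unit:
                continue
            # primitivity
            if any(u % d == 0 and unit == unit[:d] * (u // d) for d in range(1, u)):
                continue
            # count complete copies rightward
            copies = 0
            while seq[start + copies * u : start + (copies + 1) * u] == unit:
                copies += 1
            if copies < min_copies:
                continue
            end = start + copies * u
            # maximality: one more unit copy on either side must fail
            left_ok = start - u >= 0 and seq[start - u : start] == unit
            right_ok = end + u <= n and seq[end : end + u] == unit
            if left_ok or right_ok:
                continue
            out.add((start, end, unit, copies))
    return out


def brute_force_pca(matrix, n_components):
    """PCA of a data matrix via direct eigendecomposition of the covariance
    of the z-scored columns (constant columns dropped). Returns
    (coordinates, explained_variance_fractions); component signs are fixed so
    that each component's largest-magnitude loading is positive.
    """
    x = np.asarray(matrix, dtype=float)
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    z = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    cov = np.cov(z, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    for j in range(evecs.shape[1]):
        i = np.argmax(np.abs(evecs[:, j]))
        if evecs[i, j] < 0:
            evecs[:, j] = -evecs[:, j]
    coords = z @ evecs[:, :n_components]
    frac = evals / evals.sum()
    return coords, frac[:n_components]


def rank_auc(scores_pos, scores_neg):
    """AUC by direct rank comparison (probability a positive outscores a
    negative, ties at 1/2)."""
    wins = 0.0
    for p in scores_pos:
        for q in scores_neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(scores_pos) * len(scores_neg))
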