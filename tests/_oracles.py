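"""Independent oracles for the test suite.

These deliberately avoid the package's fitting code paths: the grid
maximizer evaluates the triad-model likelihood by brute-force refined grid
search with closed-form profiled stratum intercepts, and the null triad
distribution is obtained by direct enumeration of Hardy-Weinberg parental
genotypes and Mendelian transmissions.
"""

from __future__ import annotations

import itertools

import numpy as np

# Cell order is part of the model definition (shared constant, not code).
from triopoo.trio_data import CELL_ORDER

_M = np.array([c[0] for c in CELL_ORDER])
_P = np.array([c[1] for c in CELL_ORDER])
_C = np.array([c[2] for c in CELL_ORDER])

# Origin of a heterozygous child's single risk copy is determined whenever
# the parents differ: the parent with more copies must have transmitted it.
_MATERNAL = (_C == 1) & (_M > _P)
_AMBIGUOUS = (_C == 1) & (_M == 1) & (_P == 1)

# Unordered mating-type stratum per cell.
_STRATA = sorted({tuple(sorted((m, p), reverse=True)) for m, p in zip(_M, _P)})
_STRATUM_ID = np.array(
    [_STRATA.index(tuple(sorted((m, p), reverse=True))) for m, p in zip(_M, _P)]
)


def _loglik_batch(counts: np.ndarray, theta: np.ndarray, terms: tuple[str, ...]):
    """Profile log-likelihood for a batch of coefficient vectors.

    ``theta`` has columns (c1, c2, *terms).  Stratum intercepts are
    maximised analytically: exp(mu_s) = N_s / sum_{i in s} w_i.
    """
    counts = np.asarray(counts, dtype=float)
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    col = {name: theta[:, 2 + k] for k, name in enumerate(terms)}
    c1 = theta[:, 0][:, None]
    c2 = theta[:, 1][:, None]
    alpha = col.get("alpha", np.zeros(len(theta)))[:, None]
    beta = col.get("beta", np.zeros(len(theta)))[:, None]
    gamma = col.get("gamma", np.zeros(len(theta)))[:, None]

    eta = (
        c1 * (_C == 1)
        + c2 * (_C == 2)
        + alpha * _MATERNAL
        + beta * (_M == 2)
        + gamma * (_M == 1)
    )
    w = np.exp(eta)
    # The double-heterozygote cell merges its two latent transmission paths.
    amb = int(np.flatnonzero(_AMBIGUOUS)[0])
    w[:, amb] = np.exp(c1[:, 0] + gamma[:, 0]) * (np.exp(alpha[:, 0]) + 1.0)

    ll = (np.log(w) * counts).sum(axis=1)
    total = counts.sum()
    for s in range(len(_STRATA)):
        in_s = _STRATUM_ID == s
        N_s = counts[in_s].sum()
        if N_s == 0:
            continue
        T_s = w[:, in_s].sum(axis=1)
        ll += N_s * (np.log(N_s) - np.log(T_s))
    return ll - total


def grid_maximize(
    counts,
    terms: tuple[str, ...] = ("alpha", "beta", "gamma"),
    span: float = 4.0,
    points: int = 9,
    levels: int = 18,
):
    """Refined dense grid search over (c1, c2, *terms).

    Returns (max log-likelihood, argmax coefficient vector).  Each level
    lays a ``points``-per-axis grid over the current box and halves the
    half-width around the best point, so the final resolution is
    span / 2**(levels-1) per axis.
    """
    dims = 2 + len(terms)
    center = np.zeros(dims)
    width = span
    best_ll = -np.inf
    best_theta = center.copy()
    for _ in range(levels):
        axes = [np.linspace(c - width, c + width, points) for c in center]
        grid = np.array(list(itertools.product(*axes)))
        ll = _loglik_batch(counts, grid, terms)
        k = int(np.argmax(ll))
        if ll[k] > best_ll:
            best_ll = float(ll[k])
            best_theta = grid[k]
        center = grid[k]
        width /= 2.0
    return best_ll, best_theta


def triad_null_probs(maf: float) -> np.ndarray:
    """Exact 15-cell probabilities under Hardy-Weinberg random mating and
    fair Mendelian transmission (no disease effects)."""
    p = maf
    hw = [(1 - p) ** 2, 2 * p * (1 - p), p**2]
    acc: dict[tuple[int, int, int], float] = {}
    for m in range(3):
        for f in range(3):
            for ma in (0, 1):
                for pa in (0, 1):
                    pm = m / 2 if ma else 1 - m / 2
                    pf = f / 2 if pa else 1 - f / 2
                    w = hw[m] * hw[f] * pm * pf
                    key = (m, f, ma + pa)
                    acc[key] = acc.get(key, 0.0) + w
    return np.array([acc.get(cell, 0.0) for cell in CELL_ORDER])


def mendelian_child_doses(m: int, p: int) -> set[int]:
    """Possible child doses by explicit enumeration of transmitted alleles."""
    mat = {0} if m == 0 else ({1} if m == 2 else {0, 1})
    pat = {0} if p == 0 else ({1} if p == 2 else {0, 1})
    return {a + b for a in mat for b in pat}
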