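"""Exact small-sample Spearman correlation test.

With n = 6 samples the usual t approximation to the Spearman null is badly
calibrated exactly where it matters for a perfect-correlation filter: the
exact two-sided tail probability of |rho| = 1 is 2/720 ~ 0.00278, and the
next achievable |rho| (0.9429, one adjacent rank swap) already has
p = 12/720 ~ 0.0167. A cutoff of p < 0.005 therefore retains perfectly
monotone pairs and nothing else — but only under the exact permutation null,
which this module computes by full enumeration of the n! rank orders for
n <= 9 (tail counts cached per n). Tied ranks break the enumeration
shortcut, so tied inputs fall back to a seeded Monte-Carlo permutation
test; n > 9 uses the t approximation.
"""

from __future__ import annotations

import math
from functools import lru_cache
from itertools import permutations

import numpy as np
from scipy import stats

EXACT_MAX_N = 9
RHO_TOL = 1e-12


class ConstantInputError(ValueError):
    """A constant vector has no defined rank correlation."""


@lru_cache(maxsize=None)
def exact_null_distribution(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Null distribution of Spearman rho over all n! untied rank orders.

    Returns ``(rho_values, counts)`` sorted by rho; counts sum to n!.
    Only the distribution of the sum of squared rank differences is needed,
    since rho = 1 - 6*sum(d^2) / (n*(n^2-1)) without ties.
    """
    if not 2 <= n <= EXACT_MAX_N:
        raise ValueError(f"exact enumeration supported for 2 <= n <= {EXACT_MAX_N}")
    base = np.arange(1, n + 1)
    perms = np.array(list(permutations(range(1, n + 1))), dtype=np.int64)
    d2 = ((perms - base) ** 2).sum(axis=1)
    vals, counts = np.unique(d2, return_counts=True)
    rho = 1.0 - 6.0 * vals / (n * (n * n - 1))
    order = np.argsort(rho)
    return rho[order], counts[order]


def _exact_two_sided_p(rho_obs: float, n: int) -> float:
    rho, counts = exact_null_distribution(n)
    tail = counts[np.abs(rho) >= abs(rho_obs) - RHO_TOL].sum()
    return float(tail / math.factorial(n))


def _has_ties(x: np.ndarray) -> bool:
    return len(np.unique(x)) < len(x)


def spearman_exact(
    x,
    y,
    n_mc: int = 100_000,
    seed: int = 0,
) -> tuple[float, float]:
    """Spearman rho with an exact (or Monte-Carlo) permutation p-value.

    Parameters
    ----------
    x, y:
        Equal-length value vectors over the same samples, n >= 4.
    n_mc:
        Monte-Carlo draws used when either vector has tied values.
    seed:
        Seed for the Monte-Carlo fallback; irrelevant for untied input.

    Returns
    -------
    (rho, p):
        rho from average ranks; two-sided p from full enumeration of the
        n! rank orders for n <= 9, Monte-Carlo permutation under ties, and
        the t approximation for n > 9.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d vectors")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    if len(np.unique(x)) == 1 or len(np.unique(y)) == 1:
        raise ConstantInputError("constant vector: rho undefined")

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    tied = _has_ties(x) or _has_ties(y)
    if n > EXACT_MAX_N:
        if abs(abs(rho) - 1.0) <= RHO_TOL:
            return rho, 0.0
        t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
        return rho, float(2.0 * stats.t.sf(abs(t), df=n - 2))
    if not tied:
        return rho, _exact_two_sided_p(rho, n)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_mc):
        perm = rng.permutation(ry)
        r = np.corrcoef(rx, perm)[0, 1]
        if abs(r) >= abs(rho) - RHO_TOL:
            hits += 1
    return rho, float((hits + 1) / (n_mc + 1))


def is_perfect(rho: float, rho_min: float = 1.0) -> bool:
    """Whether |rho| reaches ``rho_min`` within the perfection tolerance.

    Average ranks cannot give |rho| = 1 in the presence of ties, so this
    doubles as the tie disqualification test when ``rho_min`` is 1.
    """
    return abs(rho) >= rho_min - RHO_TOL
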