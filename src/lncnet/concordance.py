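"""Cross-dataset fold-change sign concordance with an exact binomial test.

A candidate gene is concordant when the sign of its internal log2 fold
change matches the sign in an independent reference dataset. The chance
probability of "success" is estimated from the reference dataset as the
proportion of lncRNAs called differentially expressed there at all
(down + up over total), and the significance of observing k concordant
genes out of n is the exact one-sided upper binomial tail
P(X >= k), X ~ Binomial(n, p0), summed term by term — no normal
approximation. One-sided "greater" is the relevant alternative: the
question is whether concordance exceeds what membership in the reference
DE list alone would produce.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("lncnet")


@dataclass
class ConcordanceResult:
    n_candidates: int
    n_concordant: int
    p0: float
    p0_numerator: int
    p0_denominator: int
    p_value: float
    flags: pd.Series  # per-gene: True/False, or NaN when indeterminate


def count_concordant(
    internal_log2fc: pd.Series, external_log2fc: pd.Series
) -> tuple[int, int, pd.Series]:
    """Count genes whose fold-change sign agrees between datasets.

    Genes missing from the reference are dropped (and logged); genes with a
    zero fold change on either side are flagged indeterminate and excluded
    from n rather than counted discordant.
    """
    common = internal_log2fc.index.intersection(external_log2fc.index)
    dropped = internal_log2fc.index.difference(common)
    if len(dropped):
        logger.info("count_concordant: %d genes absent from reference: %s",
                    len(dropped), list(dropped))
    si = np.sign(internal_log2fc.loc[common].astype(float))
    se = np.sign(external_log2fc.loc[common].astype(float))
    determinate = (si != 0) & (se != 0)
    flags = pd.Series(np.where(determinate, si == se, np.nan), index=common)
    n = int(determinate.sum())
    k = int((flags == 1).sum())
    return n, k, flags


def estimate_p0(n_de_down: int, n_de_up: int, n_total: int) -> float:
    """Chance success probability: fraction of reference lncRNAs that are DE."""
    if n_total <= 0:
        raise ValueError("total lncRNA count must be positive")
    if min(n_de_down, n_de_up) < 0 or n_de_down + n_de_up > n_total:
        raise ValueError("inconsistent DE counts")
    p0 = (n_de_down + n_de_up) / n_total
    if not 0 < p0 < 1:
        raise ValueError(f"degenerate null probability p0={p0}")
    return p0


def binomial_concordance_test(k: int, n: int, p0: float) -> float:
    """Exact one-sided (greater) binomial tail P(X >= k), X ~ Bin(n, p0)."""
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0 < p0 < 1:
        raise ValueError("need 0 < p0 < 1")
    return float(
        sum(math.comb(n, i) * p0**i * (1.0 - p0) ** (n - i) for i in range(k, n + 1))
    )


def validate_concordance(
    internal_log2fc: pd.Series,
    external_log2fc: pd.Series,
    n_de_down: int,
    n_de_up: int,
    n_total: int,
    rounded_p0: float | None = None,
) -> ConcordanceResult:
    """Full concordance validation against a reference DE summary.

    ``rounded_p0`` overrides the full-precision ratio (e.g. 0.61 instead of
    7997/13144) for bit-matching a published figure.
    """
    n, k, flags = count_concordant(internal_log2fc, external_log2fc)
    p0 = rounded_p0 if rounded_p0 is not None else estimate_p0(n_de_down, n_de_up, n_total)
    p = binomial_concordance_test(k, n, p0) if n > 0 else 1.0
    return ConcordanceResult(
        n_candidates=n,
        n_concordant=k,
        p0=p0,
        p0_numerator=n_de_down + n_de_up,
        p0_denominator=n_total,
        p_value=p,
        flags=flags,
    )
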