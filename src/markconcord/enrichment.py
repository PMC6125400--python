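"""Hypergeometric overlap testing of gene lists against prior gene sets.

The question: given a universe of N genes, a prior set of K of them, and a
query list of n, how surprising is an overlap of k?  The answer is the
upper tail P(X >= k) of Hypergeometric(N, K, n) — the observed k included.
The universe must always be supplied explicitly (e.g. the genes present on
the expression platform); overlap p-values are meaningless without a stated
universe, so there is deliberately no default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

CORRECTIONS = {"BH": "fdr_bh", "bonferroni": "bonferroni", "none": None}


@dataclass(frozen=True)
class OverlapTest:
    """One hypergeometric overlap test, all counts restricted to the universe."""

    N: int  # universe size
    K: int  # prior-set genes in universe
    n: int  # query genes in universe
    k: int  # overlap
    p_value: float

    def __post_init__(self) -> None:
        if not self.k <= min(self.K, self.n):
            raise ValueError(f"overlap k={self.k} exceeds min(K={self.K}, n={self.n})")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value out of (0,1]: {self.p_value}")

    @property
    def percent_chance(self) -> float:
        """The p-value expressed as a percentage (100 * p)."""
        return 100.0 * self.p_value


def hypergeometric_overlap(
    query: Iterable[str], prior: Iterable[str], universe: Iterable[str]
) -> OverlapTest:
    """Upper-tail hypergeometric test of query/prior overlap within a universe.

    Genes outside the universe are dropped (with a warning) before counting.
    An empty query gives k=0, p=1.  An empty universe is an error.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    q, pr = set(query), set(prior)
    dropped = (q | pr) - uni
    if dropped:
        logger.warning("%d gene(s) outside the universe dropped", len(dropped))
    q &= uni
    pr &= uni
    N, K, n, k = len(uni), len(pr), len(q), len(q & pr)
    if not q:
        return OverlapTest(N, K, 0, 0, 1.0)
    # P(X >= k); sf is P(X > k-1)
    p = float(hypergeom.sf(k - 1, N, K, n))
    p = min(max(p, 5e-324), 1.0)  # clamp float underflow into (0, 1]
    return OverlapTest(N, K, n, k, p)


def gene_set_enrichment(
    query: Iterable[str],
    sets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    correction: str = "BH",
) -> pd.DataFrame:
    """Test a query list against several named prior sets, with multiplicity
    correction across sets (BH, bonferroni, or none).  Sets with no member in
    the universe are skipped with a warning.  Sorted by raw p."""
    if correction not in CORRECTIONS:
        raise ValueError(f"correction must be one of {sorted(CORRECTIONS)}")
    if not sets:
        raise ValueError("need at least one gene set")
    uni = set(universe)
    rows = []
    for name, members in sets.items():
        if not set(members) & uni:
            logger.warning("set %s has no members in the universe; skipped", name)
            continue
        t = hypergeometric_overlap(query, members, uni)
        rows.append(
            {"set": name, "N": t.N, "K": t.K, "n": t.n, "k": t.k, "p_value": t.p_value}
        )
    if not rows:
        raise ValueError("no gene set has members in the universe")
    df = pd.DataFrame(rows)
    method = CORRECTIONS[correction]
    if method is None:
        df["adj_p"] = df["p_value"]
    else:
        df["adj_p"] = multipletests(df["p_value"].to_numpy(), method=method)[1]
    return df.sort_values("p_value", kind="stable").reset_index(drop=True)
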