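"""Exact enrichment statistics.

Everything downstream — annotation of pathways with GO/KEGG terms, validation
of candidate drug–phenotype pairs against a reference catalogue — reduces to
the same exact combinatorial question: given ``k`` entities drawn from a
universe of ``t``, of which ``m`` carry an annotation, how surprising is it to
observe ``q`` or more annotated entities in the draw?

The upper tail

    P(X >= q) = sum_{x=q}^{min(m,k)} C(m, x) C(t-m, k-x) / C(t, k)

is evaluated in log space so it stays exact to working precision for
universes up to ~1e5 entities.  The one-tailed (enrichment-direction)
Fisher exact test on a 2x2 table is the same tail under the margin mapping
``t = a+b+c+d, m = a+c, k = a+b, q = a``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

__all__ = [
    "EnrichmentInput",
    "ContingencyTable2x2",
    "EnrichmentResult",
    "hypergeom_upper_tail",
    "fisher_one_tailed",
    "odds_ratio",
    "overlap_enrichment",
]


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


@dataclass(frozen=True)
class EnrichmentInput:
    """Counts for a hypergeometric enrichment test.

    t: universe size; m: annotated entities in the universe;
    k: query size; q: annotated entities in the query.
    """

    t: int
    m: int
    k: int
    q: int

    def __post_init__(self) -> None:
        t, m, k, q = self.t, self.m, self.k, self.q
        if t < 1:
            raise ValueError(f"universe size t must be >= 1, got {t}")
        if not (0 <= m <= t):
            raise ValueError(f"m={m} outside [0, t={t}]")
        if not (0 <= k <= t):
            raise ValueError(f"k={k} outside [0, t={t}]")
        lo = max(0, k - (t - m))
        hi = min(m, k)
        if not (lo <= q <= hi):
            raise ValueError(
                f"q={q} infeasible for t={t}, m={m}, k={k} (feasible range [{lo}, {hi}])"
            )


def hypergeom_upper_tail(t: int, m: int, k: int, q: int) -> float:
    """Exact P(X >= q) for X ~ Hypergeometric(t, m, k).

    Log-space summation over the feasible support; returns a value in (0, 1].
    Raises ``ValueError`` on infeasible counts.
    """
    EnrichmentInput(t, m, k, q)  # validates
    lo = max(0, k - (t - m))
    hi = min(m, k)
    if q <= lo:
        return 1.0
    xs = np.arange(q, hi + 1)
    log_terms = _log_comb(m, xs) + _log_comb(t - m, k - xs) - _log_comb(t, k)
    return float(min(1.0, np.exp(logsumexp(log_terms))))


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 overlap table.

    a: in query and in reference; b: in query only; c: in reference only;
    d: in neither.  a+b+c+d is the universe size.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name}={v} must be a non-negative integer")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class EnrichmentResult:
    p_value: float
    odds_ratio: float
    table: ContingencyTable2x2


def fisher_one_tailed(tab: ContingencyTable2x2) -> float:
    """One-tailed (enrichment direction) Fisher exact p-value.

    Identical to ``hypergeom_upper_tail`` with t=a+b+c+d, m=a+c, k=a+b, q=a.
    """
    if tab.total == 0:
        raise ValueError("all-zero contingency table")
    return hypergeom_upper_tail(t=tab.total, m=tab.a + tab.c, k=tab.a + tab.b, q=tab.a)


def odds_ratio(tab: ContingencyTable2x2, haldane: bool = False) -> float:
    """(a*d)/(b*c); with ``haldane`` 0.5 is added to every cell when any cell
    is zero (Haldane–Anscombe correction).  Without it, b*c == 0 is an error.
    """
    a, b, c, d = float(tab.a), float(tab.b), float(tab.c), float(tab.d)
    if haldane and min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    if b * c == 0:
        raise ValueError("odds ratio undefined for a zero off-diagonal cell (use haldane=True)")
    return (a * d) / (b * c)


def overlap_enrichment(query: set, reference: set, universe: set) -> EnrichmentResult:
    """Enrichment of ``query`` in ``reference`` against ``universe``.

    Builds the 2x2 overlap table and returns the one-tailed p-value together
    with the odds ratio (Haldane-corrected when a cell is zero, so the
    reported ratio is always finite).
    """
    if not universe:
        raise ValueError("empty universe")
    if not query:
        raise ValueError("empty query set")
    if not query <= universe:
        raise ValueError("query is not a subset of the universe")
    if not reference <= universe:
        raise ValueError("reference is not a subset of the universe")
    a = len(query & reference)
    b = len(query) - a
    c = len(reference) - a
    d = len(universe) - a - b - c
    tab = ContingencyTable2x2(a, b, c, d)
    return EnrichmentResult(
        p_value=fisher_one_tailed(tab),
        odds_ratio=odds_ratio(tab, haldane=True),
        table=tab,
    )
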