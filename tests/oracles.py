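"""Independent brute-force oracles used only by the test suite.

These deliberately share no code with the package: the hypergeometric tail
is an exact rational enumeration over subsets, and the pathway oracle is an
exhaustive DFS over all simple paths.  Both are only feasible at toy sizes,
which is the point.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb


def hypergeom_tail_exact(t: int, m: int, k: int, q: int) -> Fraction:
    """P(X >= q) as an exact rational via direct combinatorial counting."""
    total = comb(t, k)
    favourable = 0
    for x in range(q, min(m, k) + 1):
        if k - x <= t - m:
            favourable += comb(m, x) * comb(t - m, k - x)
    return Fraction(favourable, total)


# ---------------------------------------------------------------------------
# pathway construction oracle


def _all_simple_paths(adj: dict[str, dict[str, set[str]]], s: str, e: str):
    """Every simple directed path s -> e over a type-labelled adjacency."""
    out: list[tuple[str, ...]] = []

    def dfs(path: tuple[str, ...]) -> None:
        u = path[-1]
        if u == e:
            out.append(path)
            return
        for v in adj.get(u, {}):
            if v not in path:
                dfs(path + (v,))

    dfs((s,))
    return out


def _ppi_walks(ppi_adj: dict[str, set[str]], s: str, max_len: int):
    """All simple PPI paths from s with 1..max_len edges."""
    out: list[tuple[str, ...]] = []

    def dfs(path: tuple[str, ...]) -> None:
        if len(path) > 1:
            out.append(path)
        if len(path) - 1 == max_len:
            return
        for v in ppi_adj.get(path[-1], ()):
            if v not in path:
                dfs(path + (v,))

    dfs((s,))
    return out


def _surviving_curated(adj, terminal_types, s, e):
    """Terminal-filtered shortest curated paths s -> e (node sequences)."""
    if s == e:
        return []
    paths = _all_simple_paths(adj, s, e)
    if not paths:
        return []
    d = min(len(p) for p in paths)
    shortest = [p for p in paths if len(p) == d]
    return [p for p in shortest if adj[p[-2]][p[-1]] & terminal_types]


def oracle_level_records(
    curated_adj: dict[str, dict[str, set[str]]],
    curated_nodes: set[str],
    terminal_types: set[str],
    ppi_adj: dict[str, set[str]],
    starts: set[str],
    ends: set[str],
    max_prefix: int = 3,
) -> set[tuple]:
    """Exhaustive reference for one level-to-level construction.

    Returns tuples (seed_pair, ppi_prefix_len, node_sequence) for every path
    the rules retain: all terminal-filtered shortest curated paths per
    ordered pair, falling back to PPI front-augmentation with lexicographic
    (prefix length, curated length) minimisation over simple combined paths.
    """
    records: set[tuple] = set()
    for s in sorted(starts):
        for e in sorted(ends):
            if s == e:
                continue
            kept = []
            if s in curated_nodes and e in curated_nodes:
                kept = _surviving_curated(curated_adj, terminal_types, s, e)
            if kept:
                for p in kept:
                    records.add(((s, e), 0, p))
                continue
            if e not in curated_nodes:
                continue
            combos = []
            for walk in _ppi_walks(ppi_adj, s, max_prefix):
                x = walk[-1]
                if x == e or x not in curated_nodes:
                    continue
                for tail in _surviving_curated(curated_adj, terminal_types, x, e):
                    if set(walk[:-1]) & set(tail):
                        continue  # combined path must be simple
                    combos.append((len(walk) - 1, len(tail), walk + tail[1:]))
            if combos:
                best = min((pl, cl) for pl, cl, _ in combos)
                for pl, cl, nodes in combos:
                    if (pl, cl) == best:
                        records.add(((s, e), pl, nodes))
    return records
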