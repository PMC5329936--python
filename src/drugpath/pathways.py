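"""Drug-signaling pathway construction.

A drug's molecular action is modelled as signal flow across three conceptual
levels: *initiation* (target genes), *perturbation* (pharmacogenomic variant
genes and differentially expressed genes) and *destination* (disease and
side-effect genes).  The pathway is assembled from two level-to-level
segments.  For every ordered seed pair (s, e) in a segment:

1. every directed shortest path s → e in the curated network is enumerated
   (deterministic lexicographic order, capped);
2. only paths whose final interaction is pathway-terminating (transcription
   regulation or translocation by default) are retained;
3. if nothing survives — including when s is absent from the curated network
   altogether — undirected protein–protein interactions may form the *front*
   of the path, up to three PPI edges, linking s to a curated node that has a
   surviving curated path to e.  Among all such simple combined paths the
   (PPI-prefix length, curated length) pair is minimised lexicographically
   and all minimisers are kept.

The union of surviving path records over all seed pairs of both segments is
the drug-signaling pathway, with per-edge provenance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigurationError, DrugExcludedError
from .io import CuratedNetwork, DrugSeedSet, PpiNetwork

log = logging.getLogger(__name__)

PPI_EDGE_TYPE = "ppi"
SEGMENTS = ("init_to_perturb", "perturb_to_dest")

__all__ = [
    "LevelAssignment",
    "PathRecord",
    "DrugPathway",
    "PathConfig",
    "assign_levels",
    "enumerate_shortest_paths",
    "filter_terminal_paths",
    "ppi_augmented_paths",
    "build_level_pathway",
    "build_drug_pathway",
    "pathway_gene_members",
    "write_pathway",
    "read_pathway_edges",
]


@dataclass(frozen=True)
class LevelAssignment:
    """Seed genes mapped onto the three conceptual levels."""

    initiation: frozenset[str]
    perturbation: frozenset[str]
    destination: frozenset[str]


@dataclass(frozen=True)
class PathRecord:
    """One surviving start→end path with provenance.

    ``node_sequence`` covers the optional PPI prefix plus the curated
    portion; the first ``ppi_prefix_len`` edges are PPI edges.
    """

    node_sequence: tuple[str, ...]
    edge_sequence: tuple[tuple[str, str, str], ...]
    ppi_prefix_len: int
    segment: str
    seed_pair: tuple[str, str]

    def sort_key(self):
        return (self.segment, self.seed_pair, self.ppi_prefix_len, self.node_sequence)


@dataclass
class DrugPathway:
    """The constructed drug-signaling subgraph with per-edge provenance."""

    drug_id: str
    nodes: set[str] = field(default_factory=set)
    edges: set[tuple[str, str, str, str]] = field(default_factory=set)  # (s, t, type, origin)
    provenance: list[PathRecord] = field(default_factory=list)
    unconnected_pairs: dict[str, int] = field(default_factory=dict)
    truncated_pairs: dict[str, int] = field(default_factory=dict)

    @property
    def is_empty(self) -> bool:
        return not self.edges


@dataclass(frozen=True)
class PathConfig:
    max_paths: int = 100
    max_ppi_prefix: int = 3
    expand_complexes: bool = True

    def __post_init__(self) -> None:
        if self.max_paths < 1:
            raise ConfigurationError("max_paths must be >= 1")
        if self.max_ppi_prefix < 1:
            raise ConfigurationError("max_ppi_prefix must be >= 1")


def assign_levels(seeds: DrugSeedSet) -> LevelAssignment:
    """TG → initiation, VG ∪ DEG → perturbation, DisG ∪ SEG → destination.

    A drug missing any of its five categories is excluded from construction.
    """
    empty = seeds.empty_categories()
    if empty:
        raise DrugExcludedError(
            f"drug {seeds.drug_id!r} has empty seed categories: {', '.join(empty)}"
        )
    return LevelAssignment(
        initiation=frozenset(seeds.tg),
        perturbation=frozenset(seeds.vg | seeds.deg),
        destination=frozenset(seeds.disg | seeds.seg),
    )


# ---------------------------------------------------------------------------
# shortest-path machinery


def _reverse_bfs_distances(net: CuratedNetwork, end: str) -> dict[str, int]:
    """Directed distance of every node TO ``end`` along curated edges."""
    dist = {end: 0}
    frontier = [end]
    radj = net.reverse_adjacency
    while frontier:
        nxt = []
        for v in frontier:
            for u in radj.get(v, ()):
                if u not in dist:
                    dist[u] = dist[v] + 1
                    nxt.append(u)
        frontier = nxt
    return dist


def enumerate_shortest_paths(
    net: CuratedNetwork,
    start: str,
    end: str,
    max_paths: int = 100,
    _dist_to_end: dict[str, int] | None = None,
) -> tuple[list[tuple[str, ...]], bool]:
    """All directed shortest paths start→end, lexicographically sorted.

    Returns ``(paths, truncated)``; paths is empty when unreachable.  The
    optional precomputed reverse-BFS distance map avoids repeated searches
    when many starts share one end.
    """
    if start == end:
        raise ValueError("degenerate seed pair: start == end")
    for n in (start, end):
        if n not in net.node_types:
            raise KeyError(f"node {n!r} not in curated network")
    dist = _dist_to_end if _dist_to_end is not None else _reverse_bfs_distances(net, end)
    if start not in dist:
        return [], False
    adj = net.adjacency
    paths: list[tuple[str, ...]] = []
    truncated = False

    # walk the shortest-path DAG: follow u→v only when it decreases dist-to-end
    stack: list[tuple[str, ...]] = [(start,)]
    # depth-first with lexicographically sorted successors yields sorted output
    def extend(prefix: tuple[str, ...]) -> bool:
        nonlocal truncated
        u = prefix[-1]
        if u == end:
            paths.append(prefix)
            if len(paths) >= max_paths:
                return False
            return True
        du = dist[u]
        for v in sorted(adj.get(u, ())):
            if dist.get(v, -1) == du - 1:
                if not extend(prefix + (v,)):
                    truncated = True
                    return False
        return True

    extend((start,))
    return paths, truncated


def _hop_types(net: CuratedNetwork, u: str, v: str) -> set[str]:
    return net.adjacency.get(u, {}).get(v, set())


def _edge_sequence(net: CuratedNetwork, nodes: tuple[str, ...]) -> tuple[tuple[str, str, str], ...]:
    """Representative typed edges for a node path.

    For the last hop a terminal type is preferred (lexicographically smallest
    terminal); elsewhere the smallest type.  Parallel interaction types are
    thereby resolved deterministically.
    """
    edges = []
    for i in range(len(nodes) - 1):
        u, v = nodes[i], nodes[i + 1]
        types = _hop_types(net, u, v)
        if i == len(nodes) - 2:
            terminal = sorted(types & net.terminal_types)
            chosen = terminal[0] if terminal else min(types)
        else:
            chosen = min(types)
        edges.append((u, v, chosen))
    return tuple(edges)


def _records_from_node_paths(
    net: CuratedNetwork,
    node_paths: list[tuple[str, ...]],
    segment: str,
    seed_pair: tuple[str, str],
) -> list[PathRecord]:
    return [
        PathRecord(
            node_sequence=p,
            edge_sequence=_edge_sequence(net, p),
            ppi_prefix_len=0,
            segment=segment,
            seed_pair=seed_pair,
        )
        for p in node_paths
    ]


def filter_terminal_paths(
    paths: list[PathRecord], terminal_types: frozenset[str] | set[str]
) -> list[PathRecord]:
    """Keep only paths whose final interaction is pathway-terminating."""
    return [p for p in paths if p.edge_sequence and p.edge_sequence[-1][2] in terminal_types]


# ---------------------------------------------------------------------------
# PPI front-augmentation


def _ppi_simple_paths(ppi: PpiNetwork, start: str, length: int) -> list[tuple[str, ...]]:
    """All simple PPI paths from ``start`` with exactly ``length`` edges."""
    out: list[tuple[str, ...]] = []

    def walk(prefix: tuple[str, ...]) -> None:
        if len(prefix) - 1 == length:
            out.append(prefix)
            return
        for nb in sorted(ppi.neighbors(prefix[-1])):
            if nb not in prefix:
                walk(prefix + (nb,))

    walk((start,))
    return out


def ppi_augmented_paths(
    start: str,
    end: str,
    net: CuratedNetwork,
    ppi: PpiNetwork,
    max_prefix: int = 3,
    max_paths: int = 100,
    segment: str = SEGMENTS[0],
    _survivor_cache: dict | None = None,
    _dist_to_end: dict[str, int] | None = None,
) -> tuple[list[PathRecord], bool]:
    """PPI-prefixed paths for a pair with no surviving curated path.

    Scans prefix lengths 1..max_prefix in order; at the first length where a
    simple combined path exists whose curated tail is a surviving
    terminal-filtered shortest path, returns every combination achieving the
    minimal curated length (lexicographic order, capped).
    """
    if max_prefix < 1:
        raise ConfigurationError("max_prefix must be >= 1")
    if end not in net.node_types:
        return [], False
    dist = _dist_to_end if _dist_to_end is not None else _reverse_bfs_distances(net, end)
    cache = _survivor_cache if _survivor_cache is not None else {}

    def survivors(x: str) -> list[tuple[str, ...]]:
        """Terminal-filtered shortest curated node paths x→end (memoised)."""
        key = (x, end)
        if key not in cache:
            if x not in dist:
                cache[key] = []
            else:
                node_paths, _ = enumerate_shortest_paths(
                    net, x, end, max_paths=max_paths, _dist_to_end=dist
                )
                kept = []
                for p in node_paths:
                    types = _hop_types(net, p[-2], p[-1])
                    if types & net.terminal_types:
                        kept.append(p)
                cache[key] = kept
        return cache[key]

    for prefix_len in range(1, max_prefix + 1):
        combos: list[tuple[tuple[str, ...], tuple[str, ...]]] = []
        for prefix in _ppi_simple_paths(ppi, start, prefix_len):
            x = prefix[-1]
            if x == end or x not in net.node_types:
                continue
            for tail in survivors(x):
                # combined path must be simple
                if set(prefix[:-1]) & set(tail):
                    continue
                combos.append((prefix, tail))
        if combos:
            best = min(len(tail) for _, tail in combos)
            records = []
            for prefix, tail in sorted(c for c in combos if len(c[1]) == best):
                nodes = prefix + tail[1:]
                ppi_edges = tuple(
                    (prefix[i], prefix[i + 1], PPI_EDGE_TYPE) for i in range(prefix_len)
                )
                records.append(
                    PathRecord(
                        node_sequence=nodes,
                        edge_sequence=ppi_edges + _edge_sequence(net, tail),
                        ppi_prefix_len=prefix_len,
                        segment=segment,
                        seed_pair=(start, end),
                    )
                )
            truncated = len(records) > max_paths
            return records[:max_paths], truncated
    return [], False


# ---------------------------------------------------------------------------
# level and drug assembly


@dataclass
class SegmentResult:
    records: list[PathRecord] = field(default_factory=list)
    unconnected_pairs: int = 0
    truncated_pairs: int = 0


def build_level_pathway(
    net: CuratedNetwork,
    ppi: PpiNetwork,
    starts: set[str] | frozenset[str],
    ends: set[str] | frozenset[str],
    segment: str,
    config: PathConfig = PathConfig(),
) -> SegmentResult:
    """Connect every ordered (start, end) seed pair under the path rules.

    Pairs with start == end are skipped; pairs yielding nothing are counted
    but not fatal.
    """
    if not starts or not ends:
        raise ValueError("starts and ends must be non-empty")
    result = SegmentResult()
    seen: set[PathRecord] = set()
    survivor_cache: dict = {}
    for end in sorted(ends):
        dist = _reverse_bfs_distances(net, end) if end in net.node_types else {}
        for start in sorted(starts):
            if start == end:
                continue
            records: list[PathRecord] = []
            truncated = False
            if start in net.node_types and end in net.node_types:
                node_paths, truncated = enumerate_shortest_paths(
                    net, start, end, max_paths=config.max_paths, _dist_to_end=dist
                )
                candidates = _records_from_node_paths(net, node_paths, segment, (start, end))
                records = filter_terminal_paths(candidates, net.terminal_types)
            if not records:
                records, truncated = ppi_augmented_paths(
                    start,
                    end,
                    net,
                    ppi,
                    max_prefix=config.max_ppi_prefix,
                    max_paths=config.max_paths,
                    segment=segment,
                    _survivor_cache=survivor_cache,
                    _dist_to_end=dist if end in net.node_types else None,
                )
            if truncated:
                result.truncated_pairs += 1
            if not records:
                result.unconnected_pairs += 1
                continue
            for r in records:
                if r not in seen:
                    seen.add(r)
                    result.records.append(r)
    result.records.sort(key=PathRecord.sort_key)
    return result


def build_drug_pathway(
    seeds: DrugSeedSet,
    net: CuratedNetwork,
    ppi: PpiNetwork,
    config: PathConfig = PathConfig(),
) -> DrugPathway:
    """Union of the initiation→perturbation and perturbation→destination
    segments, with full provenance."""
    levels = assign_levels(seeds)
    seg1 = build_level_pathway(
        net, ppi, levels.initiation, levels.perturbation, SEGMENTS[0], config
    )
    seg2 = build_level_pathway(
        net, ppi, levels.perturbation, levels.destination, SEGMENTS[1], config
    )
    pw = DrugPathway(drug_id=seeds.drug_id)
    pw.unconnected_pairs = {SEGMENTS[0]: seg1.unconnected_pairs, SEGMENTS[1]: seg2.unconnected_pairs}
    pw.truncated_pairs = {SEGMENTS[0]: seg1.truncated_pairs, SEGMENTS[1]: seg2.truncated_pairs}
    for rec in seg1.records + seg2.records:
        pw.provenance.append(rec)
        pw.nodes.update(rec.node_sequence)
        for i, (s, t, ity) in enumerate(rec.edge_sequence):
            origin = "ppi" if i < rec.ppi_prefix_len else "curated"
            pw.edges.add((s, t, ity, origin))
    if pw.is_empty:
        log.warning("drug %s: no surviving paths in either segment", seeds.drug_id)
    return pw


def pathway_gene_members(
    p: DrugPathway, net: CuratedNetwork, expand_complexes: bool = True
) -> set[str]:
    """Gene-type members of a pathway.

    Complex nodes contribute their member genes when ``expand_complexes``;
    compounds and RNAs are excluded.  Nodes absent from the curated network
    entered via the PPI front and are genes by construction.
    """
    genes: set[str] = set()
    for n in p.nodes:
        ntype = net.node_types.get(n, "gene")
        if ntype == "gene":
            genes.add(n)
        elif ntype == "complex" and expand_complexes:
            genes |= net.complex_members.get(n, set())
    return genes


# ---------------------------------------------------------------------------
# serialisation


def write_pathway(p: DrugPathway, out_dir: str | Path) -> tuple[Path, Path]:
    """Edge-list TSV plus JSON summary for one drug pathway."""
    out = Path(out_dir)
    edge_segments: dict[tuple[str, str, str, str], set[str]] = {}
    for rec in p.provenance:
        for i, (s, t, ity) in enumerate(rec.edge_sequence):
            origin = "ppi" if i < rec.ppi_prefix_len else "curated"
            edge_segments.setdefault((s, t, ity, origin), set()).add(rec.segment)
    tsv = out / f"{p.drug_id}.pathway.tsv"
    lines = ["source\ttarget\tinteraction_type\torigin\tsegment"]
    for (s, t, ity, origin), segs in sorted(edge_segments.items()):
        lines.append("\t".join((s, t, ity, origin, "|".join(sorted(segs)))))
    tsv.write_text("\n".join(lines) + "\n", encoding="utf-8")
    summary = {
        "drug_id": p.drug_id,
        "n_nodes": len(p.nodes),
        "n_edges": len(p.edges),
        "n_paths": len(p.provenance),
        "unconnected_pairs": p.unconnected_pairs,
        "truncated_pairs": p.truncated_pairs,
        "empty": p.is_empty,
    }
    js = out / f"{p.drug_id}.summary.json"
    js.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return tsv, js


def read_pathway_edges(path: str | Path) -> DrugPathway:
    """Reload a pathway edge list (node/edge sets only; no provenance)."""
    p = Path(path)
    drug_id = p.name.split(".pathway.tsv")[0]
    pw = DrugPathway(drug_id=drug_id)
    with open(p, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("source\t"):
            raise ValueError(f"{p} does not look like a pathway edge list")
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 5:
                continue
            s, t, ity, origin, _seg = cols
            pw.edges.add((s, t, ity, origin))
            pw.nodes.update((s, t))
    return pw
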