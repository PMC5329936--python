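"""Readers and writers for the textual formats the pipeline consumes.

Formats
-------
* Curated network: tab-separated, SIF-like rows
  ``source<TAB>interaction_type<TAB>target[<TAB>source_type<TAB>target_type]``.
  Complex membership is encoded with interaction_type ``has_member`` in the
  same file; isolated nodes survive round trips through ``#node`` directive
  lines.  Node types default to ``gene`` when never declared.
* Protein–protein interactions: two-column TSV of gene pairs (undirected).
* Gene sets (drug seed categories, GO-BP-like and KEGG-like catalogues): GMT.
* Drug–phenotype associations: two-column TSV, optional header.

Identifiers are opaque strings throughout; no symbol normalisation is
attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .errors import ParseError, ValidationError

log = logging.getLogger(__name__)

NODE_TYPES = frozenset({"gene", "compound", "complex", "rna"})
DEFAULT_TERMINAL_TYPES = frozenset({"transcription_regulation", "translocation"})
MEMBERSHIP_TYPE = "has_member"

SEED_CATEGORIES = ("tg", "vg", "deg", "disg", "seg")


# ---------------------------------------------------------------------------
# containers


@dataclass
class CuratedNetwork:
    """Directed, node- and edge-typed interaction network.

    ``edges`` holds (source, target, interaction_type) triples; several
    interaction types may connect the same ordered node pair.  ``adjacency``
    collapses them to ``{u: {v: {types}}}`` for traversal.
    """

    node_types: dict[str, str] = field(default_factory=dict)
    edges: set[tuple[str, str, str]] = field(default_factory=set)
    terminal_types: frozenset[str] = DEFAULT_TERMINAL_TYPES
    complex_members: dict[str, set[str]] = field(default_factory=dict)
    _adj: dict | None = field(default=None, repr=False, compare=False)
    _radj: dict | None = field(default=None, repr=False, compare=False)

    def validate(self) -> "CuratedNetwork":
        for s, t, ity in self.edges:
            for n in (s, t):
                if n not in self.node_types:
                    raise ValidationError(f"edge endpoint {n!r} has no declared node type")
        for cx in self.complex_members:
            if self.node_types.get(cx) != "complex":
                raise ValidationError(f"complex_members key {cx!r} is not typed 'complex'")
        for nt in self.node_types.values():
            if nt not in NODE_TYPES:
                raise ValidationError(f"unknown node type {nt!r}")
        return self

    @property
    def nodes(self) -> set[str]:
        return set(self.node_types)

    def genes(self) -> set[str]:
        return {n for n, t in self.node_types.items() if t == "gene"}

    @property
    def adjacency(self) -> dict[str, dict[str, set[str]]]:
        if self._adj is None:
            adj: dict[str, dict[str, set[str]]] = {}
            for s, t, ity in self.edges:
                adj.setdefault(s, {}).setdefault(t, set()).add(ity)
            self._adj = adj
        return self._adj

    @property
    def reverse_adjacency(self) -> dict[str, set[str]]:
        if self._radj is None:
            radj: dict[str, set[str]] = {}
            for s, t, _ in self.edges:
                radj.setdefault(t, set()).add(s)
            self._radj = radj
        return self._radj

    def graph(self) -> nx.DiGraph:
        """The network as a networkx DiGraph (edge attr ``types``)."""
        g = nx.DiGraph()
        for n, t in self.node_types.items():
            g.add_node(n, node_type=t)
        for u, targets in self.adjacency.items():
            for v, types in targets.items():
                g.add_edge(u, v, types=frozenset(types))
        return g


@dataclass
class PpiNetwork:
    """Undirected protein–protein interaction network over gene ids."""

    edges: set[tuple[str, str]] = field(default_factory=set)  # stored sorted
    self_loops_dropped: int = 0
    _adj: dict | None = field(default=None, repr=False, compare=False)

    @staticmethod
    def canonical(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str) -> None:
        if a == b:
            self.self_loops_dropped += 1
            return
        self.edges.add(self.canonical(a, b))
        self._adj = None

    @property
    def nodes(self) -> set[str]:
        return {n for e in self.edges for n in e}

    @property
    def adjacency(self) -> dict[str, set[str]]:
        if self._adj is None:
            adj: dict[str, set[str]] = {}
            for a, b in self.edges:
                adj.setdefault(a, set()).add(b)
                adj.setdefault(b, set()).add(a)
            self._adj = adj
        return self._adj

    def neighbors(self, n: str) -> set[str]:
        return self.adjacency.get(n, set())

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_edges_from(self.edges)
        return g


@dataclass
class DrugSeedSet:
    """A drug's five seed gene categories.

    tg: target genes; vg: pharmacogenomic variant genes; deg: differentially
    expressed genes; disg: disease genes; seg: side-effect genes.
    """

    drug_id: str
    tg: set[str] = field(default_factory=set)
    vg: set[str] = field(default_factory=set)
    deg: set[str] = field(default_factory=set)
    disg: set[str] = field(default_factory=set)
    seg: set[str] = field(default_factory=set)

    def categories(self) -> dict[str, set[str]]:
        return {c: getattr(self, c) for c in SEED_CATEGORIES}

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for c in SEED_CATEGORIES:
            out |= getattr(self, c)
        return out

    def empty_categories(self) -> list[str]:
        return [c for c in SEED_CATEGORIES if not getattr(self, c)]


@dataclass
class AssociationSet:
    """Deduplicated drug–phenotype pairs of one kind (indication/side_effect)."""

    pairs: set[tuple[str, str]] = field(default_factory=set)
    phenotype_kind: str = "indication"

    def __post_init__(self) -> None:
        if self.phenotype_kind not in ("indication", "side_effect"):
            raise ValidationError(f"unknown phenotype kind {self.phenotype_kind!r}")

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.pairs

    def drugs(self) -> set[str]:
        return {d for d, _ in self.pairs}

    def phenotypes(self) -> set[str]:
        return {p for _, p in self.pairs}

    def of_drug(self, drug_id: str) -> set[str]:
        return {p for d, p in self.pairs if d == drug_id}

    def restricted(self, drugs: set[str], phenotypes: set[str]) -> "AssociationSet":
        kept = {(d, p) for d, p in self.pairs if d in drugs and p in phenotypes}
        return AssociationSet(kept, self.phenotype_kind)


# ---------------------------------------------------------------------------
# curated network


def _data_lines(path: str | Path):
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            yield lineno, line


def read_curated_network(
    path: str | Path,
    terminal_types: frozenset[str] | set[str] = DEFAULT_TERMINAL_TYPES,
) -> CuratedNetwork:
    """Parse a typed directed edge list into a validated CuratedNetwork.

    Rows have 3 columns (source, interaction_type, target) or 5 (plus
    source_type, target_type).  ``has_member`` rows record complex membership
    instead of a signalling edge.  Duplicate edges collapse.
    """
    node_types: dict[str, str] = {}
    declared: dict[str, str] = {}
    edges: set[tuple[str, str, str]] = set()
    complex_members: dict[str, set[str]] = {}

    def declare(node: str, ntype: str, lineno: int) -> None:
        if ntype not in NODE_TYPES:
            raise ValidationError(f"line {lineno}: unknown node type {ntype!r} for {node!r}")
        prev = declared.get(node)
        if prev is not None and prev != ntype:
            raise ValidationError(
                f"line {lineno}: node {node!r} redeclared as {ntype!r} (was {prev!r})"
            )
        declared[node] = ntype

    for lineno, line in _data_lines(path):
        if line.startswith("#"):
            cols = line.split("\t")
            if cols[0] == "#node":
                if len(cols) != 3:
                    raise ParseError(f"line {lineno}: #node directive needs id and type")
                declare(cols[1], cols[2], lineno)
                node_types.setdefault(cols[1], cols[2])
            continue
        cols = line.split("\t")
        if len(cols) not in (3, 5):
            raise ParseError(
                f"line {lineno}: expected 3 or 5 tab-separated columns, got {len(cols)}"
            )
        src, ity, tgt = cols[0], cols[1], cols[2]
        if len(cols) == 5:
            declare(src, cols[3], lineno)
            declare(tgt, cols[4], lineno)
        if ity == MEMBERSHIP_TYPE:
            declare(src, "complex", lineno)
            complex_members.setdefault(src, set()).add(tgt)
        else:
            edges.add((src, tgt, ity))
        for n in (src, tgt):
            node_types.setdefault(n, "")

    for n in node_types:
        node_types[n] = declared.get(n, "gene")
    # membership sources were force-declared complex above; members default gene
    net = CuratedNetwork(
        node_types=node_types,
        edges=edges,
        terminal_types=frozenset(terminal_types),
        complex_members=complex_members,
    ).validate()
    log.info(
        "read curated network %s: %d nodes, %d edges, %d complexes",
        path, len(net.node_types), len(net.edges), len(net.complex_members),
    )
    return net


def write_curated_network(net: CuratedNetwork, path: str | Path) -> None:
    attached: set[str] = set()
    lines: list[str] = []
    for s, t, ity in sorted(net.edges):
        lines.append(
            "\t".join((s, ity, t, net.node_types[s], net.node_types[t]))
        )
        attached.update((s, t))
    for cx in sorted(net.complex_members):
        for member in sorted(net.complex_members[cx]):
            lines.append(
                "\t".join((cx, MEMBERSHIP_TYPE, member, "complex", net.node_types.get(member, "gene")))
            )
            attached.update((cx, member))
    for n in sorted(set(net.node_types) - attached):
        lines.append(f"#node\t{n}\t{net.node_types[n]}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


# ---------------------------------------------------------------------------
# PPI


def read_ppi_network(path: str | Path) -> PpiNetwork:
    """Two-column TSV of undirected gene pairs; self-pairs dropped, counted."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"PPI file does not exist: {p}")
    net = PpiNetwork()
    seen_rows = 0
    for lineno, line in _data_lines(p):
        if line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 2:
            raise ParseError(f"line {lineno}: expected 2 columns, got {len(cols)}")
        seen_rows += 1
        net.add(cols[0], cols[1])
    if seen_rows == 0:
        raise ParseError(f"PPI file {p} exists but contains no data rows")
    if net.self_loops_dropped:
        log.warning("dropped %d self-pairs from %s", net.self_loops_dropped, p)
    return net


def write_ppi_network(net: PpiNetwork, path: str | Path) -> None:
    lines = ["\t".join(e) for e in sorted(net.edges)]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Standard GMT (name, description, members...) into {set_id: members}."""
    out: dict[str, set[str]] = {}
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) < 2:
            raise ParseError(f"line {lineno}: GMT rows need at least name and description")
        name = cols[0]
        if name in out:
            raise ParseError(f"line {lineno}: duplicate gene-set id {name!r}")
        out[name] = {g for g in cols[2:] if g}
    return out


def write_gene_sets(sets: dict[str, set[str]], path: str | Path, description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *sorted(members)])
        for name, members in sorted(sets.items())
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def read_drug_seed_sets(path: str | Path) -> list[DrugSeedSet]:
    """Seed GMT with set ids ``<drug_id>::<CATEGORY>`` into DrugSeedSets.

    Categories may be empty (such drugs are later rejected by the pathway
    builder's admission filter, not by the parser).
    """
    raw = read_gene_sets(path)
    drugs: dict[str, DrugSeedSet] = {}
    for set_id, members in raw.items():
        if "::" not in set_id:
            raise ParseError(f"seed set id {set_id!r} is not of the form drug::CATEGORY")
        drug_id, cat = set_id.rsplit("::", 1)
        cat = cat.lower()
        if cat not in SEED_CATEGORIES:
            raise ParseError(f"unknown seed category {cat!r} in {set_id!r}")
        seeds = drugs.setdefault(drug_id, DrugSeedSet(drug_id))
        getattr(seeds, cat).update(members)
    return [drugs[d] for d in sorted(drugs)]


def write_drug_seed_sets(seed_sets: list[DrugSeedSet], path: str | Path) -> None:
    gmt: dict[str, set[str]] = {}
    for s in seed_sets:
        for cat, members in s.categories().items():
            gmt[f"{s.drug_id}::{cat.upper()}"] = members
    # upper-case category suffix is cosmetic; reader lower-cases it
    write_gene_sets(gmt, path)


# ---------------------------------------------------------------------------
# associations

_HEADERS = {("drug_id", "phenotype_id"), ("drug", "phenotype")}


def read_association_table(path: str | Path, phenotype_kind: str) -> AssociationSet:
    """Two-column drug_id/phenotype_id TSV (optional header) into a set."""
    pairs: set[tuple[str, str]] = set()
    first = True
    for lineno, line in _data_lines(path):
        if line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 2:
            raise ParseError(f"line {lineno}: expected 2 columns, got {len(cols)}")
        if first and (cols[0].lower(), cols[1].lower()) in _HEADERS:
            first = False
            continue
        first = False
        pairs.add((cols[0], cols[1]))
    return AssociationSet(pairs, phenotype_kind)


def write_association_table(assoc: AssociationSet, path: str | Path) -> None:
    lines = ["drug_id\tphenotype_id"]
    lines += ["\t".join(p) for p in sorted(assoc.pairs)]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
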