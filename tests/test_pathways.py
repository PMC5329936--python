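"""Pathway construction: level assignment, shortest-path enumeration,
terminal filtering, PPI front-augmentation and whole-drug assembly."""

import numpy as np
import pytest

from conftest import make_curated, make_ppi
from drugpath.errors import ConfigurationError, DrugExcludedError
from drugpath.io import DrugSeedSet, PpiNetwork
from drugpath.pathways import (
    PathConfig,
    assign_levels,
    build_drug_pathway,
    build_level_pathway,
    enumerate_shortest_paths,
    filter_terminal_paths,
    pathway_gene_members,
    ppi_augmented_paths,
    read_pathway_edges,
    write_pathway,
)
from oracles import oracle_level_records

TR = "transcription_regulation"


class TestAssignLevels:
    def test_three_level_mapping(self):
        seeds = DrugSeedSet("d", tg={"a"}, vg={"b"}, deg={"c"}, disg={"d"}, seg={"e"})
        lv = assign_levels(seeds)
        assert lv.initiation == {"a"}
        assert lv.perturbation == {"b", "c"}
        assert lv.destination == {"d", "e"}

    def test_union_dedup(self):
        seeds = DrugSeedSet("d", tg={"a"}, vg={"b"}, deg={"b"}, disg={"d"}, seg={"e"})
        assert assign_levels(seeds).perturbation == {"b"}

    def test_empty_category_excludes_drug(self):
        seeds = DrugSeedSet("d", tg={"a"}, vg={"b"}, deg={"c"}, disg={"d"}, seg=set())
        with pytest.raises(DrugExcludedError, match="seg"):
            assign_levels(seeds)


class TestEnumerateShortestPaths:
    def test_chain(self, chain_net):
        paths, truncated = enumerate_shortest_paths(chain_net, "a", "c")
        assert paths == [("a", "b", "c")]
        assert not truncated

    def test_diamond_all_shortest(self):
        net = make_curated(
            [("a", "x", "b"), ("b", "x", "d"), ("a", "x", "c"), ("c", "x", "d")]
        )
        paths, _ = enumerate_shortest_paths(net, "a", "d")
        assert paths == [("a", "b", "d"), ("a", "c", "d")]  # lexicographic

    def test_longer_route_ignored(self):
        net = make_curated(
            [("a", "x", "b"), ("b", "x", "c"), ("a", "x", "c")]
        )
        paths, _ = enumerate_shortest_paths(net, "a", "c")
        assert paths == [("a", "c")]

    def test_unreachable_gives_empty(self):
        net = make_curated([("a", "x", "b"), ("c", "x", "d")])
        assert enumerate_shortest_paths(net, "a", "d") == ([], False)

    def test_degenerate_pair_errors(self, chain_net):
        with pytest.raises(ValueError):
            enumerate_shortest_paths(chain_net, "a", "a")

    def test_truncation_flag(self):
        # 2x2x2 lattice of parallel 2-hop routes: 3 shortest paths a->d via b1..b3
        edges = [("a", "x", f"b{i}") for i in range(3)]
        edges += [(f"b{i}", "x", "d") for i in range(3)]
        net = make_curated(edges)
        paths, truncated = enumerate_shortest_paths(net, "a", "d", max_paths=2)
        assert len(paths) == 2 and truncated

    def test_respects_direction(self):
        net = make_curated([("b", "x", "a")])
        assert enumerate_shortest_paths(net, "a", "b")[0] == []


class TestTerminalFilter:
    def test_keeps_terminal_drops_other(self):
        net = make_curated([("a", "x", "b"), ("b", TR, "c"), ("a", "x", "c")])
        paths, _ = enumerate_shortest_paths(net, "a", "c")
        from drugpath.pathways import _records_from_node_paths

        records = _records_from_node_paths(net, paths, "init_to_perturb", ("a", "c"))
        kept = filter_terminal_paths(records, net.terminal_types)
        assert [r.node_sequence for r in kept] == []  # shortest is the direct non-terminal hop
        paths2, _ = enumerate_shortest_paths(net, "b", "c")
        records2 = _records_from_node_paths(net, paths2, "init_to_perturb", ("b", "c"))
        kept2 = filter_terminal_paths(records2, net.terminal_types)
        assert [r.node_sequence for r in kept2] == [("b", "c")]

    def test_parallel_type_prefers_terminal_on_last_hop(self):
        net = make_curated([("a", "binding", "b"), ("a", TR, "b")])
        paths, _ = enumerate_shortest_paths(net, "a", "b")
        from drugpath.pathways import _records_from_node_paths

        (rec,) = _records_from_node_paths(net, paths, "init_to_perturb", ("a", "b"))
        assert rec.edge_sequence[-1][2] == TR

    def test_empty_input(self):
        assert filter_terminal_paths([], {TR}) == []


class TestPpiAugmentation:
    def test_single_ppi_prefix(self):
        net = make_curated([("x", TR, "y")])
        ppi = make_ppi([("s", "x")])
        records, _ = ppi_augmented_paths("s", "y", net, ppi)
        assert len(records) == 1
        rec = records[0]
        assert rec.node_sequence == ("s", "x", "y")
        assert rec.ppi_prefix_len == 1
        assert rec.edge_sequence[0] == ("s", "x", "ppi")
        assert rec.edge_sequence[-1][2] == TR

    def test_prefix_beyond_three_rejected(self):
        net = make_curated([("x", TR, "y")])
        # s - p1 - p2 - p3 - x: distance 4 to the curated entry point
        ppi = make_ppi([("s", "p1"), ("p1", "p2"), ("p2", "p3"), ("p3", "x")])
        records, _ = ppi_augmented_paths("s", "y", net, ppi)
        assert records == []

    def test_prefix_minimality_before_curated_length(self):
        # entry u at PPI distance 2 with 1-hop curated path; entry v at
        # distance 1 with 2-hop curated path: shorter prefix wins
        net = make_curated([("u", TR, "y"), ("v", "x", "w"), ("w", TR, "y")])
        ppi = make_ppi([("s", "v"), ("s", "m"), ("m", "u")])
        records, _ = ppi_augmented_paths("s", "y", net, ppi)
        assert [r.node_sequence for r in records] == [("s", "v", "w", "y")]
        assert records[0].ppi_prefix_len == 1

    def test_bad_max_prefix(self):
        net = make_curated([("x", TR, "y")])
        with pytest.raises(ConfigurationError):
            ppi_augmented_paths("s", "y", net, PpiNetwork(), max_prefix=0)


class TestBuildLevelPathway:
    def test_simple_chain(self, chain_net, empty_ppi):
        res = build_level_pathway(chain_net, empty_ppi, {"a"}, {"c"}, "init_to_perturb")
        assert [r.node_sequence for r in res.records] == [("a", "b", "c")]

    def test_no_connection_is_not_fatal(self, empty_ppi):
        net = make_curated([("a", "binding", "b")])
        res = build_level_pathway(net, empty_ppi, {"a"}, {"b"}, "init_to_perturb")
        assert res.records == [] and res.unconnected_pairs == 1

    @pytest.mark.parametrize("trial", range(60))
    def test_matches_exhaustive_oracle_on_random_graphs(self, trial):
        """Deep check of the full rule set against brute-force DFS search."""
        rng = np.random.default_rng(1000 + trial)
        records, oracle = _build_and_oracle(rng)
        assert records == oracle


def _build_and_oracle(rng):
    """Random <=12-node instance -> (implementation records, oracle records)."""
    n = int(rng.integers(5, 13))
    nodes = [chr(ord("A") + i) for i in range(n)]
    types = ["binding", "activation", TR, "translocation"]
    edges = []
    for u in nodes:
        for v in nodes:
            if u != v and rng.random() < 0.22:
                edges.append((u, types[int(rng.integers(4))], v))
    curated = make_curated(edges) if edges else make_curated([("A", "binding", "B")])
    ppi_pairs = []
    extra = [f"z{i}" for i in range(3)]  # genes outside the curated network
    pool = nodes + extra
    for _ in range(int(rng.integers(3, 12))):
        a, b = rng.choice(len(pool), size=2, replace=False)
        ppi_pairs.append((pool[int(a)], pool[int(b)]))
    ppi = make_ppi(ppi_pairs)
    starts = set(rng.choice(pool, size=2, replace=False))
    ends = set(rng.choice(nodes, size=2, replace=False))

    res = build_level_pathway(
        curated, ppi, starts, ends, "init_to_perturb", PathConfig(max_paths=5000)
    )
    got = {(r.seed_pair, r.ppi_prefix_len, r.node_sequence) for r in res.records}
    want = oracle_level_records(
        curated.adjacency, curated.nodes, set(curated.terminal_types),
        ppi.adjacency, starts, ends,
    )
    return got, want


class TestBuildDrugPathway:
    def test_union_of_segments_with_provenance(self, empty_ppi):
        net = make_curated([("a", TR, "b"), ("b", TR, "d")])
        seeds = DrugSeedSet("d1", tg={"a"}, vg={"b"}, deg={"b"}, disg={"d"}, seg={"d"})
        pw = build_drug_pathway(seeds, net, empty_ppi)
        assert pw.nodes == {"a", "b", "d"}
        assert {e[:2] for e in pw.edges} == {("a", "b"), ("b", "d")}
        assert {r.segment for r in pw.provenance} == {"init_to_perturb", "perturb_to_dest"}

    def test_shared_edge_stored_once_two_provenance_records(self, empty_ppi):
        # the a -> b terminal edge serves both segments: init {a} -> perturb
        # {a, b} and perturb {a, b} -> dest {b}
        net = make_curated([("a", TR, "b")])
        seeds = DrugSeedSet("d1", tg={"a"}, vg={"a"}, deg={"b"}, disg={"b"}, seg={"b"})
        pw = build_drug_pathway(seeds, net, empty_ppi)
        # same path appears in both segments; edge set deduplicates
        assert len(pw.edges) == 1
        assert len(pw.provenance) == 2

    def test_empty_pathway_flagged(self, empty_ppi):
        net = make_curated([("a", "binding", "b")])
        seeds = DrugSeedSet("d1", tg={"a"}, vg={"b"}, deg={"b"}, disg={"a"}, seg={"a"})
        pw = build_drug_pathway(seeds, net, empty_ppi)
        assert pw.is_empty

    def test_excluded_drug_propagates(self, chain_net, empty_ppi):
        seeds = DrugSeedSet("d1", tg=set(), vg={"b"}, deg={"c"}, disg={"c"}, seg={"c"})
        with pytest.raises(DrugExcludedError):
            build_drug_pathway(seeds, chain_net, empty_ppi)


class TestGeneMembers:
    def test_type_filtering_and_complex_expansion(self, empty_ppi):
        net = make_curated(
            [("g1", "x", "c1"), ("c1", "x", "K"), ("K", TR, "g9")],
            node_types={"c1": "compound", "K": "complex"},
            complex_members={"K": {"m1", "m2"}},
        )
        seeds = DrugSeedSet("d", tg={"g1"}, vg={"g9"}, deg={"g9"}, disg={"g9"}, seg={"g9"})
        pw = build_drug_pathway(seeds, net, empty_ppi)
        assert pathway_gene_members(pw, net, expand_complexes=True) == {"g1", "g9", "m1", "m2"}
        assert pathway_gene_members(pw, net, expand_complexes=False) == {"g1", "g9"}

    def test_empty_pathway_no_members(self, empty_ppi):
        net = make_curated([("a", "binding", "b")])
        seeds = DrugSeedSet("d", tg={"a"}, vg={"b"}, deg={"b"}, disg={"a"}, seg={"a"})
        pw = build_drug_pathway(seeds, net, empty_ppi)
        assert pathway_gene_members(pw, net) == set()


class TestSerialisation:
    def test_write_and_reload_edges(self, tmp_path, chain_net, empty_ppi, toy_seeds):
        net = make_curated([("a", TR, "b"), ("b", TR, "d"), ("b", TR, "e")])
        seeds = DrugSeedSet("d1", tg={"a"}, vg={"b"}, deg={"b"}, disg={"d"}, seg={"e"})
        pw = build_drug_pathway(seeds, net, empty_ppi)
        tsv, js = write_pathway(pw, tmp_path)
        assert js.exists()
        back = read_pathway_edges(tsv)
        assert back.edges == pw.edges
        assert back.nodes == pw.nodes
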