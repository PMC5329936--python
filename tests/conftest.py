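import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from drugpath.io import CuratedNetwork, DrugSeedSet, PpiNetwork
from drugpath.synthetic import SyntheticConfig, generate_bundle


def make_curated(edges, node_types=None, terminal_types=frozenset({"transcription_regulation", "translocation"}), complex_members=None):
    """Small-network helper: edges as (src, type, tgt) triples."""
    nt = dict(node_types or {})
    es = set()
    for s, ity, t in edges:
        es.add((s, t, ity))
        nt.setdefault(s, "gene")
        nt.setdefault(t, "gene")
    return CuratedNetwork(
        node_types=nt,
        edges=es,
        terminal_types=frozenset(terminal_types),
        complex_members={k: set(v) for k, v in (complex_members or {}).items()},
    ).validate()


def make_ppi(pairs):
    net = PpiNetwork()
    for a, b in pairs:
        net.add(a, b)
    return net


@pytest.fixture
def chain_net():
    """a -activation-> b -transcription_regulation-> c."""
    return make_curated([("a", "activation", "b"), ("b", "transcription_regulation", "c")])


@pytest.fixture
def empty_ppi():
    return PpiNetwork()


@pytest.fixture
def toy_seeds():
    return DrugSeedSet("drugA", tg={"a"}, vg={"b"}, deg={"c"}, disg={"d"}, seg={"e"})


@pytest.fixture(scope="session")
def small_bundle():
    """A scaled-down bundle for fast end-to-end tests (8 drugs)."""
    cfg = SyntheticConfig(
        rng_seed=11,
        n_genes=240,
        n_compounds=16,
        n_complexes=8,
        n_rnas=6,
        n_curated_edges=1100,
        n_ppi_edges=600,
        n_drugs=8,
        n_clusters=2,
        n_modules=6,
        n_phenotypes=20,
        planted_associations_per_cluster=4,
    )
    return generate_bundle(cfg)


@pytest.fixture(scope="session")
def default_bundle():
    """The standard study conditions: generator defaults, fixed seed."""
    return generate_bundle(SyntheticConfig(rng_seed=0))
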