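"""Synthetic fixture bundles with planted, recoverable structure.

Real inputs to this kind of pipeline (curated signaling interactions,
protein–protein interactions, per-drug seed gene sets, GO/KEGG catalogues,
known and reference drug–phenotype associations) come from licensed,
versioned databases.  This module generates self-contained stand-ins that
reproduce the statistical structure the method consumes:

* a typed directed curated network with hub structure (preferential
  attachment by default) and a controlled fraction of pathway-terminating
  edge types;
* an undirected PPI network over the gene pool;
* drugs organised into clusters that share a configurable fraction of their
  seed genes, so intra-cluster pathway similarity is elevated;
* cluster-shared phenotype associations, split per phenotype into *known*
  pairs (given to the transfer step) and withheld *planted-truth* pairs that
  a correct pipeline should rediscover; the *reference* set is the planted
  truth plus noise.

Everything is deterministic given ``rng_seed``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .io import (
    AssociationSet,
    CuratedNetwork,
    DrugSeedSet,
    PpiNetwork,
    read_association_table,
    read_curated_network,
    read_drug_seed_sets,
    read_gene_sets,
    read_ppi_network,
    write_association_table,
    write_curated_network,
    write_drug_seed_sets,
    write_gene_sets,
    write_ppi_network,
)

log = logging.getLogger(__name__)

TERMINAL_TYPES = ("transcription_regulation", "translocation")
GENERIC_TYPES = ("activation", "inhibition", "binding", "modification")

# fraction of a drug's seed-gene total apportioned to each category; the
# expression category dominates, mirroring top/bottom-ranked probe-set lists
CATEGORY_FRACTIONS = {"tg": 0.08, "vg": 0.12, "deg": 0.45, "disg": 0.20, "seg": 0.15}

__all__ = [
    "SyntheticConfig",
    "FixtureBundle",
    "generate_networks",
    "generate_drug_seeds",
    "generate_catalogs",
    "generate_reference_associations",
    "generate_bundle",
    "write_fixture_bundle",
    "read_fixture_bundle",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the generator; defaults define the standard study conditions.

    ``seed_total_mean``/``seed_total_sd`` calibrate the per-drug seed-gene
    total (165 +/- 43 genes per drug), scaled by ``size_factor`` so test
    bundles stay small.
    """

    rng_seed: int = 0
    n_genes: int = 600
    n_compounds: int = 40
    n_complexes: int = 20
    n_rnas: int = 12
    n_curated_edges: int = 2600
    terminal_edge_fraction: float = 0.25
    n_ppi_edges: int = 1500
    n_drugs: int = 20
    n_clusters: int = 4
    seed_total_mean: float = 165.0
    seed_total_sd: float = 43.0
    size_factor: float = 0.2
    cluster_overlap: float = 0.7
    n_phenotypes: int = 40
    planted_associations_per_cluster: int = 6
    background_known_per_drug: int = 2
    reference_noise_rate: float = 0.1
    topology: str = "preferential"  # or "erdos"
    n_modules: int = 12
    within_module_bias: float = 0.85

    def __post_init__(self) -> None:
        for name in (
            "n_genes", "n_curated_edges", "n_ppi_edges", "n_drugs",
            "n_clusters", "n_phenotypes", "planted_associations_per_cluster",
        ):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("terminal_edge_fraction", "cluster_overlap", "reference_noise_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.topology not in ("preferential", "erdos"):
            raise ConfigurationError(f"unknown topology {self.topology!r}")
        if self.n_modules < 1:
            raise ConfigurationError("n_modules must be positive")
        if not (0.0 <= self.within_module_bias <= 1.0):
            raise ConfigurationError("within_module_bias must lie in [0, 1]")


@dataclass
class FixtureBundle:
    config: SyntheticConfig
    curated: CuratedNetwork
    ppi: PpiNetwork
    seeds: list[DrugSeedSet]
    clusters: dict[str, int]
    go_catalog: dict[str, set[str]]
    kegg_catalog: dict[str, set[str]]
    indication_phenotypes: list[str]
    side_effect_phenotypes: list[str]
    known_indications: AssociationSet = field(default_factory=lambda: AssociationSet(set(), "indication"))
    reference_indications: AssociationSet = field(default_factory=lambda: AssociationSet(set(), "indication"))
    planted_indications: AssociationSet = field(default_factory=lambda: AssociationSet(set(), "indication"))
    known_side_effects: AssociationSet = field(default_factory=lambda: AssociationSet(set(), "side_effect"))
    reference_side_effects: AssociationSet = field(default_factory=lambda: AssociationSet(set(), "side_effect"))
    planted_side_effects: AssociationSet = field(default_factory=lambda: AssociationSet(set(), "side_effect"))

    def drug_ids(self) -> list[str]:
        return [s.drug_id for s in self.seeds]


# ---------------------------------------------------------------------------
# networks


def node_module(node_id: str, n_modules: int) -> int:
    """Deterministic module assignment from the numeric part of a node id.

    Synthetic signaling networks are built modular — edges fall mostly within
    a module — because real curated pathway collections are; drug clusters
    later seed from distinct modules, keeping unrelated drugs' pathways apart.
    """
    return int(node_id[1:]) % n_modules


def generate_networks(cfg: SyntheticConfig) -> tuple[CuratedNetwork, PpiNetwork]:
    """Typed directed curated network plus undirected PPI, deterministic."""
    rng = np.random.default_rng(cfg.rng_seed)
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]
    compounds = [f"C{i:03d}" for i in range(cfg.n_compounds)]
    complexes = [f"X{i:03d}" for i in range(cfg.n_complexes)]
    rnas = [f"R{i:03d}" for i in range(cfg.n_rnas)]
    node_types = {n: "gene" for n in genes}
    node_types |= {n: "compound" for n in compounds}
    node_types |= {n: "complex" for n in complexes}
    node_types |= {n: "rna" for n in rnas}
    nodes = sorted(node_types)
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    max_pairs = n * (n - 1)
    if cfg.n_curated_edges > max_pairs:
        raise ConfigurationError(
            f"cannot place {cfg.n_curated_edges} directed edges over {n} nodes"
        )

    modules: dict[int, list[int]] = {}
    for v, i in index.items():
        modules.setdefault(node_module(v, cfg.n_modules), []).append(i)

    pairs: set[tuple[str, str]] = set()
    degree = np.ones(n)  # +1 smoothing so isolated nodes stay reachable
    attempts = 0
    while len(pairs) < cfg.n_curated_edges:
        attempts += 1
        if attempts > 50 * cfg.n_curated_edges:
            raise ConfigurationError("edge sampling failed to converge; graph too dense")
        si = int(rng.integers(n))
        s = nodes[si]
        if rng.random() < cfg.within_module_bias:
            candidates = modules[node_module(s, cfg.n_modules)]
        else:
            candidates = range(n)
        candidates = np.asarray(candidates)
        if cfg.topology == "preferential":
            w = degree[candidates]
            ti = int(candidates[int(rng.choice(len(candidates), p=w / w.sum()))])
        else:
            ti = int(candidates[int(rng.integers(len(candidates)))])
        t = nodes[ti]
        if s == t or (s, t) in pairs:
            continue
        pairs.add((s, t))
        degree[ti] += 1
        degree[si] += 1

    edges: set[tuple[str, str, str]] = set()
    for s, t in sorted(pairs):
        if rng.random() < cfg.terminal_edge_fraction:
            ity = TERMINAL_TYPES[int(rng.integers(len(TERMINAL_TYPES)))]
        else:
            ity = GENERIC_TYPES[int(rng.integers(len(GENERIC_TYPES)))]
        edges.add((s, t, ity))

    complex_members = {
        cx: set(rng.choice(genes, size=int(rng.integers(2, 6)), replace=False))
        for cx in complexes
    }
    curated = CuratedNetwork(
        node_types=node_types,
        edges=edges,
        terminal_types=frozenset(TERMINAL_TYPES),
        complex_members=complex_members,
    ).validate()

    max_ppi = cfg.n_genes * (cfg.n_genes - 1) // 2
    if cfg.n_ppi_edges > max_ppi:
        raise ConfigurationError(
            f"cannot place {cfg.n_ppi_edges} PPI edges over {cfg.n_genes} genes"
        )
    ppi = PpiNetwork()
    attempts = 0
    while len(ppi.edges) < cfg.n_ppi_edges:
        attempts += 1
        if attempts > 50 * cfg.n_ppi_edges:
            raise ConfigurationError("PPI sampling failed to converge")
        a, b = rng.choice(cfg.n_genes, size=2, replace=False)
        ppi.add(genes[int(a)], genes[int(b)])
    ppi.self_loops_dropped = 0
    return curated, ppi


# ---------------------------------------------------------------------------
# drugs


def _category_sizes(cfg: SyntheticConfig, rng: np.random.Generator) -> dict[str, int]:
    total = max(10.0, rng.normal(cfg.seed_total_mean, cfg.seed_total_sd)) * cfg.size_factor
    total = max(5, int(round(total)))
    sizes = {c: max(1, int(round(total * f))) for c, f in CATEGORY_FRACTIONS.items()}
    return sizes


def generate_drug_seeds(
    cfg: SyntheticConfig, curated: CuratedNetwork, ppi: PpiNetwork
) -> tuple[list[DrugSeedSet], dict[str, int]]:
    """Clustered seed sets; every drug has all five categories non-empty.

    Drugs within a cluster draw a ``cluster_overlap`` fraction of each
    category from a shared cluster pool, the remainder from the global gene
    pool, so cluster-mates build similar pathways.
    """
    rng = np.random.default_rng(cfg.rng_seed + 1)
    gene_pool = sorted(curated.genes() | ppi.nodes)
    if len(gene_pool) < 20:
        raise ConfigurationError("gene pool too small for seed generation")

    # clusters own disjoint blocks of network modules; their shared seed pools
    # are drawn inside those modules so cluster-mates' pathways localise there
    per_cluster = max(1, cfg.n_modules // cfg.n_clusters)
    module_genes: dict[int, list[str]] = {m: [] for m in range(cfg.n_modules)}
    for g in gene_pool:
        module_genes[node_module(g, cfg.n_modules)].append(g)

    cluster_pools: list[dict[str, list[str]]] = []
    for c in range(cfg.n_clusters):
        own_modules = [(c * per_cluster + i) % cfg.n_modules for i in range(per_cluster)]
        own_genes = sorted(g for m in own_modules for g in module_genes[m])
        ref_sizes = _category_sizes(cfg, rng)
        pools = {}
        for cat, size in ref_sizes.items():
            pool_size = min(len(own_genes), max(2, int(round(size * 1.3))))
            pools[cat] = sorted(rng.choice(own_genes, size=pool_size, replace=False))
        cluster_pools.append(pools)

    seeds: list[DrugSeedSet] = []
    clusters: dict[str, int] = {}
    for i in range(cfg.n_drugs):
        drug_id = f"D{i:02d}"
        cluster = i % cfg.n_clusters
        clusters[drug_id] = cluster
        sizes = _category_sizes(cfg, rng)
        if max(sizes.values()) > len(gene_pool):
            raise ConfigurationError("category size exceeds gene pool")
        drug = DrugSeedSet(drug_id)
        for cat, size in sizes.items():
            pool = cluster_pools[cluster][cat]
            n_shared = min(len(pool), int(round(size * cfg.cluster_overlap)))
            shared = set(rng.choice(pool, size=n_shared, replace=False)) if n_shared else set()
            n_rest = max(0, size - len(shared))
            rest = set(rng.choice(gene_pool, size=n_rest, replace=False)) if n_rest else set()
            getattr(drug, cat).update(shared | rest)
        seeds.append(drug)
    return seeds, clusters


def generate_catalogs(
    cfg: SyntheticConfig, curated: CuratedNetwork, ppi: PpiNetwork
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """GO-BP-like and KEGG-like annotation catalogues over the gene pool.

    Each term is anchored to one network module (most members drawn from it,
    the rest global), mirroring how real annotation terms describe the
    functional modules that pathways run through; a pathway localised in a
    module is then genuinely enriched for that module's terms, which is what
    the GO/KEGG similarity measures compare.
    """
    rng = np.random.default_rng(cfg.rng_seed + 2)
    gene_pool = sorted(curated.genes() | ppi.nodes)
    module_genes: dict[int, list[str]] = {m: [] for m in range(cfg.n_modules)}
    for g in gene_pool:
        module_genes[node_module(g, cfg.n_modules)].append(g)

    def make_term(size: int) -> set[str]:
        module = int(rng.integers(cfg.n_modules))
        own = module_genes[module]
        n_mod = min(len(own), max(1, int(round(size * 0.7))))
        members = set(rng.choice(own, size=n_mod, replace=False))
        n_rest = max(0, size - n_mod)
        if n_rest:
            members |= set(rng.choice(gene_pool, size=n_rest, replace=False))
        return members

    go = {f"GOBP:{i:04d}": make_term(int(rng.integers(10, 41))) for i in range(80)}
    kegg = {f"KEGG:{i:04d}": make_term(int(rng.integers(10, 51))) for i in range(40)}
    return go, kegg


# ---------------------------------------------------------------------------
# associations


def generate_reference_associations(
    cfg: SyntheticConfig,
    drug_ids: list[str],
    clusters: dict[str, int],
    phenotype_kind: str = "indication",
    seed_offset: int = 3,
) -> tuple[AssociationSet, AssociationSet, AssociationSet, list[str]]:
    """Known, reference and withheld planted-truth association sets.

    Each cluster shares planted phenotypes; for each planted phenotype the
    cluster's drugs are split into known holders and withheld drugs, the
    withheld pairs forming the planted truth the pipeline should recover.
    The reference set is the planted truth plus noise pairs
    (``reference_noise_rate`` noise pairs per planted pair, rounded).
    """
    rng = np.random.default_rng(cfg.rng_seed + seed_offset)
    prefix = "IND" if phenotype_kind == "indication" else "SE"
    vocab = [f"{prefix}:{i:03d}" for i in range(cfg.n_phenotypes)]
    known: set[tuple[str, str]] = set()
    planted: set[tuple[str, str]] = set()

    by_cluster: dict[int, list[str]] = {}
    for d in drug_ids:
        by_cluster.setdefault(clusters[d], []).append(d)

    for cluster in sorted(by_cluster):
        members = sorted(by_cluster[cluster])
        n_ph = min(cfg.planted_associations_per_cluster, len(vocab))
        phenos = rng.choice(vocab, size=n_ph, replace=False)
        for ph in phenos:
            order = list(rng.permutation(members))
            if len(order) < 2:
                known.update((d, str(ph)) for d in order)
                continue
            n_known = max(1, len(order) // 2)
            known.update((d, str(ph)) for d in order[:n_known])
            planted.update((d, str(ph)) for d in order[n_known:])

    # background known pairs (random, avoid planted so known ∩ truth stays empty)
    for d in drug_ids:
        placed = 0
        while placed < cfg.background_known_per_drug:
            ph = vocab[int(rng.integers(len(vocab)))]
            if (d, ph) in planted or (d, ph) in known:
                placed += 1  # slot forfeited; keeps the loop bounded
                continue
            known.add((d, ph))
            placed += 1

    reference = set(planted)
    n_noise = int(round(cfg.reference_noise_rate * len(planted)))
    guard = 0
    while n_noise > 0 and guard < 1000:
        guard += 1
        d = drug_ids[int(rng.integers(len(drug_ids)))]
        ph = vocab[int(rng.integers(len(vocab)))]
        pair = (d, ph)
        if pair in reference or pair in known:
            continue
        reference.add(pair)
        n_noise -= 1

    return (
        AssociationSet(known, phenotype_kind),
        AssociationSet(reference, phenotype_kind),
        AssociationSet(planted, phenotype_kind),
        vocab,
    )


# ---------------------------------------------------------------------------
# bundles


def generate_bundle(cfg: SyntheticConfig) -> FixtureBundle:
    """Generate a complete fixture bundle for one configuration."""
    curated, ppi = generate_networks(cfg)
    seeds, clusters = generate_drug_seeds(cfg, curated, ppi)
    go, kegg = generate_catalogs(cfg, curated, ppi)
    drug_ids = [s.drug_id for s in seeds]
    k_ind, r_ind, p_ind, ind_vocab = generate_reference_associations(
        cfg, drug_ids, clusters, "indication", seed_offset=3
    )
    k_se, r_se, p_se, se_vocab = generate_reference_associations(
        cfg, drug_ids, clusters, "side_effect", seed_offset=4
    )
    return FixtureBundle(
        config=cfg,
        curated=curated,
        ppi=ppi,
        seeds=seeds,
        clusters=clusters,
        go_catalog=go,
        kegg_catalog=kegg,
        indication_phenotypes=ind_vocab,
        side_effect_phenotypes=se_vocab,
        known_indications=k_ind,
        reference_indications=r_ind,
        planted_indications=p_ind,
        known_side_effects=k_se,
        reference_side_effects=r_se,
        planted_side_effects=p_se,
    )


BUNDLE_FILES = {
    "curated": "network.tsv",
    "ppi": "ppi.tsv",
    "seeds": "seeds.gmt",
    "go": "go.gmt",
    "kegg": "kegg.gmt",
    "known_indications": "known_indications.tsv",
    "reference_indications": "reference_indications.tsv",
    "planted_indications": "planted_indications.tsv",
    "known_side_effects": "known_side_effects.tsv",
    "reference_side_effects": "reference_side_effects.tsv",
    "planted_side_effects": "planted_side_effects.tsv",
}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_fixture_bundle(bundle: FixtureBundle, out_dir: str | Path) -> dict:
    """Write every bundle file plus a manifest with config and checksums."""
    out = Path(out_dir)
    if not out.is_dir():
        raise FileNotFoundError(f"output directory does not exist: {out}")
    write_curated_network(bundle.curated, out / BUNDLE_FILES["curated"])
    write_ppi_network(bundle.ppi, out / BUNDLE_FILES["ppi"])
    write_drug_seed_sets(bundle.seeds, out / BUNDLE_FILES["seeds"])
    write_gene_sets(bundle.go_catalog, out / BUNDLE_FILES["go"])
    write_gene_sets(bundle.kegg_catalog, out / BUNDLE_FILES["kegg"])
    for key in (
        "known_indications", "reference_indications", "planted_indications",
        "known_side_effects", "reference_side_effects", "planted_side_effects",
    ):
        write_association_table(getattr(bundle, key), out / BUNDLE_FILES[key])
    manifest = {
        "config": dataclasses.asdict(bundle.config),
        "rng_seed": bundle.config.rng_seed,
        "clusters": bundle.clusters,
        "indication_phenotypes": bundle.indication_phenotypes,
        "side_effect_phenotypes": bundle.side_effect_phenotypes,
        "checksums": {name: _sha256(out / name) for name in sorted(BUNDLE_FILES.values())},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest


def read_fixture_bundle(in_dir: str | Path) -> FixtureBundle:
    """Reload a written bundle; round-trips to the generated objects."""
    d = Path(in_dir)
    manifest = json.loads((d / "manifest.json").read_text(encoding="utf-8"))
    cfg = SyntheticConfig(**manifest["config"])
    return FixtureBundle(
        config=cfg,
        curated=read_curated_network(d / BUNDLE_FILES["curated"]),
        ppi=read_ppi_network(d / BUNDLE_FILES["ppi"]),
        seeds=read_drug_seed_sets(d / BUNDLE_FILES["seeds"]),
        clusters={k: int(v) for k, v in manifest["clusters"].items()},
        go_catalog=read_gene_sets(d / BUNDLE_FILES["go"]),
        kegg_catalog=read_gene_sets(d / BUNDLE_FILES["kegg"]),
        indication_phenotypes=list(manifest["indication_phenotypes"]),
        side_effect_phenotypes=list(manifest["side_effect_phenotypes"]),
        known_indications=read_association_table(d / BUNDLE_FILES["known_indications"], "indication"),
        reference_indications=read_association_table(d / BUNDLE_FILES["reference_indications"], "indication"),
        planted_indications=read_association_table(d / BUNDLE_FILES["planted_indications"], "indication"),
        known_side_effects=read_association_table(d / BUNDLE_FILES["known_side_effects"], "side_effect"),
        reference_side_effects=read_association_table(d / BUNDLE_FILES["reference_side_effects"], "side_effect"),
        planted_side_effects=read_association_table(d / BUNDLE_FILES["planted_side_effects"], "side_effect"),
    )
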