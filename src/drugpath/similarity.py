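"""Pathway similarity measures.

Two drugs are compared through their constructed signaling pathways in three
ways, each a Jaccard coefficient between binary membership profiles:

* ``gene``  — membership of gene-type pathway members (Gene-Sim);
* ``go``    — membership of GO-BP-like terms enriched in the pathway's genes
  (GO-Sim, hypergeometric P < alpha, default 0.01, no correction);
* ``kegg``  — membership of enriched KEGG-like pathways (KEGG-Sim), same test.

The Jaccard coefficient of two membership sets is independent of the profile
universe, so the universe only matters for profile storage and for the
enrichment background.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import CuratedNetwork, PpiNetwork
from .pathways import DrugPathway, pathway_gene_members
from .stats import hypergeom_upper_tail

log = logging.getLogger(__name__)

MEASURES = ("gene", "go", "kegg")

__all__ = [
    "MEASURES",
    "BinaryProfile",
    "SimilarityMatrix",
    "membership_vector",
    "jaccard",
    "jaccard_sets",
    "enriched_term_set",
    "pathway_feature_set",
    "pathway_similarity",
    "similarity_matrix",
    "gene_universe",
]


@dataclass(frozen=True)
class BinaryProfile:
    """Membership indicator over a sorted, deduplicated feature universe."""

    universe: tuple[str, ...]
    bits: tuple[bool, ...]

    def members(self) -> set[str]:
        return {f for f, b in zip(self.universe, self.bits) if b}


def membership_vector(
    members: set[str], universe: list[str] | tuple[str, ...], strict: bool = False
) -> BinaryProfile:
    """Binary profile of ``members`` over ``universe`` (sorted, deduplicated).

    Members outside the universe raise when ``strict``; otherwise they are
    ignored and counted in a log message.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    uni = tuple(sorted(set(universe)))
    outside = members - set(uni)
    if outside:
        if strict:
            raise ValidationError(
                f"members outside universe: {', '.join(sorted(outside)[:5])}"
            )
        log.debug("membership_vector: %d members outside universe ignored", len(outside))
    inset = members & set(uni)
    return BinaryProfile(universe=uni, bits=tuple(f in inset for f in uni))


def jaccard(a: BinaryProfile, b: BinaryProfile) -> float:
    """|A ∩ B| / |A ∪ B| on identical universes; both-empty convention is 0."""
    if a.universe != b.universe:
        raise ValidationError("profiles have different universes")
    return jaccard_sets(a.members(), b.members())


def jaccard_sets(a: set[str], b: set[str]) -> float:
    union = len(a | b)
    if union == 0:
        return 0.0
    return len(a & b) / union


def enriched_term_set(
    genes: set[str],
    catalog: dict[str, set[str]],
    universe: set[str],
    alpha: float = 0.01,
    correct: str | None = None,
) -> set[str]:
    """Terms whose overlap with ``genes`` is hypergeometrically enriched.

    For each term the test uses t=|universe|, m=|term ∩ universe|,
    k=|genes|, q=|term ∩ genes|; terms with zero overlap are never returned.
    ``correct="bh"`` applies Benjamini–Hochberg to the tested terms (off by
    default: the raw-alpha behaviour mirrors classical enrichment annotation
    tools).
    """
    if not universe:
        raise ValueError("empty universe")
    if not genes <= universe:
        raise ValueError("query genes must lie within the universe")
    t = len(universe)
    k = len(genes)
    tested: list[tuple[str, float]] = []
    for term in sorted(catalog):
        members = catalog[term] & universe
        q = len(members & genes)
        if q == 0:
            continue
        p = hypergeom_upper_tail(t=t, m=len(members), k=k, q=q)
        tested.append((term, p))
    if correct is None:
        return {term for term, p in tested if p < alpha}
    if correct == "bh":
        if not tested:
            return set()
        terms, ps = zip(*tested)
        order = np.argsort(ps, kind="stable")
        n = len(ps)
        adj = np.empty(n)
        running = 1.0
        for rank_idx in range(n - 1, -1, -1):
            i = order[rank_idx]
            running = min(running, ps[i] * n / (rank_idx + 1))
            adj[i] = running
        return {terms[i] for i in range(n) if adj[i] < alpha}
    raise ValueError(f"unknown correction {correct!r}")


def gene_universe(net: CuratedNetwork, ppi: PpiNetwork | None = None) -> set[str]:
    """Default gene universe: gene-type curated nodes plus all PPI genes."""
    uni = net.genes()
    if ppi is not None:
        uni |= ppi.nodes
    return uni


def pathway_feature_set(
    pathway: DrugPathway,
    measure: str,
    net: CuratedNetwork,
    catalogs: dict[str, dict[str, set[str]]] | None = None,
    universe: set[str] | None = None,
    alpha: float = 0.01,
    expand_complexes: bool = True,
) -> set[str]:
    """The membership set underlying one measure's binary profile."""
    if measure not in MEASURES:
        raise ValueError(f"unknown measure {measure!r}; expected one of {MEASURES}")
    genes = pathway_gene_members(pathway, net, expand_complexes=expand_complexes)
    if measure == "gene":
        return genes
    if catalogs is None or measure not in catalogs:
        raise ValueError(f"measure {measure!r} needs an annotation catalog")
    uni = universe if universe is not None else gene_universe(net)
    return enriched_term_set(genes & uni, catalogs[measure], uni, alpha=alpha)


def pathway_similarity(
    p1: DrugPathway,
    p2: DrugPathway,
    measure: str,
    net: CuratedNetwork,
    catalogs: dict[str, dict[str, set[str]]] | None = None,
    universe: set[str] | None = None,
    alpha: float = 0.01,
    expand_complexes: bool = True,
) -> float:
    """Jaccard similarity of two pathways under one measure."""
    f1 = pathway_feature_set(p1, measure, net, catalogs, universe, alpha, expand_complexes)
    f2 = pathway_feature_set(p2, measure, net, catalogs, universe, alpha, expand_complexes)
    return jaccard_sets(f1, f2)


@dataclass
class SimilarityMatrix:
    """Symmetric matrix of pairwise Jaccard similarities for one measure."""

    drugs: list[str]
    values: np.ndarray
    measure: str

    def index_of(self, drug_id: str) -> int:
        return self.drugs.index(drug_id)

    def get(self, d1: str, d2: str) -> float:
        return float(self.values[self.index_of(d1), self.index_of(d2)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.drugs, columns=self.drugs)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.6f", index_label="drug_id")

    @classmethod
    def read_tsv(cls, path, measure: str) -> "SimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(drugs=list(df.index), values=df.to_numpy(dtype=float), measure=measure)


def similarity_matrix(
    pathways: list[DrugPathway],
    measure: str,
    net: CuratedNetwork,
    catalogs: dict[str, dict[str, set[str]]] | None = None,
    universe: set[str] | None = None,
    alpha: float = 0.01,
    expand_complexes: bool = True,
) -> SimilarityMatrix:
    """Pairwise similarity over all drugs with non-empty pathways.

    Drugs whose pathway is empty have undefined similarity and are excluded
    (logged), not scored 0.  Each unordered pair is computed once; the
    diagonal is 1 for drugs with a non-empty feature set.
    """
    if not pathways:
        raise ValueError("need at least one pathway")
    kept = [p for p in pathways if not p.is_empty]
    dropped = [p.drug_id for p in pathways if p.is_empty]
    if dropped:
        log.warning("similarity: excluding %d empty pathways: %s", len(dropped), dropped)
    kept.sort(key=lambda p: p.drug_id)
    features = [
        pathway_feature_set(p, measure, net, catalogs, universe, alpha, expand_complexes)
        for p in kept
    ]
    n = len(kept)
    vals = np.zeros((n, n))
    for i in range(n):
        vals[i, i] = 1.0 if features[i] else 0.0
        for j in range(i + 1, n):
            vals[i, j] = vals[j, i] = jaccard_sets(features[i], features[j])
    return SimilarityMatrix(drugs=[p.drug_id for p in kept], values=vals, measure=measure)
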