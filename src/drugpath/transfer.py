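"""Similarity-based transfer of drug–phenotype associations.

The prediction procedure: for each similarity measure, every known
association (d1, phenotype) is assigned to every other drug d2 with
similarity(d1, d2) at or above a threshold; assignments already known are
removed.  The threshold for each measure is chosen by scanning a grid and
minimising the one-tailed enrichment p-value of the candidate set against an
independent reference association set.  Only pairs proposed by all three
measures at their chosen thresholds become predictions.  Indications and
side effects run through the identical machinery, differing only in the
known/reference sets supplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import UntestableThresholdError
from .io import AssociationSet
from .similarity import MEASURES, SimilarityMatrix
from .stats import EnrichmentResult, overlap_enrichment

log = logging.getLogger(__name__)

__all__ = [
    "ThresholdScan",
    "PredictionSet",
    "default_grid",
    "transfer_associations",
    "candidate_enrichment",
    "select_threshold",
    "predict_intersection",
    "predict_associations",
    "precision_recall",
    "harmonic_f1",
]


def default_grid() -> list[float]:
    """Similarity thresholds 0.00 .. 1.00 in steps of 0.01."""
    return [round(i / 100, 2) for i in range(101)]


@dataclass
class ThresholdScan:
    """Grid scan of candidate enrichment for one similarity measure.

    ``p_at[i]`` is None where the threshold was untestable (no candidates).
    """

    measure: str
    grid: list[float]
    p_at: list[float | None] = field(default_factory=list)
    candidate_count_at: list[int] = field(default_factory=list)
    chosen: float | None = None

    def to_dict(self) -> dict:
        return {
            "measure": self.measure,
            "grid": self.grid,
            "p_at": self.p_at,
            "candidate_count_at": self.candidate_count_at,
            "chosen": self.chosen,
        }


@dataclass
class PredictionSet:
    """Final predictions: the three-way intersection of per-measure candidates."""

    pairs: set[tuple[str, str]]
    per_measure_sets: dict[str, set[tuple[str, str]]]
    thresholds: dict[str, float]


def transfer_associations(
    sim: SimilarityMatrix, known: AssociationSet, theta: float
) -> set[tuple[str, str]]:
    """Assign each drug's known phenotypes to all sufficiently similar drugs.

    For every ordered drug pair (d1, d2), d1 != d2, with similarity >= theta,
    d1's known phenotypes become candidates for d2; candidates already known
    are removed, so the result is disjoint from ``known``.
    """
    if not (0.0 <= theta <= 1.0):
        raise ValueError(f"theta must lie in [0, 1], got {theta}")
    candidates: set[tuple[str, str]] = set()
    drugs = sim.drugs
    known_by_drug = {d: known.of_drug(d) for d in drugs}
    for i, d1 in enumerate(drugs):
        phenotypes = known_by_drug[d1]
        if not phenotypes:
            continue
        row = sim.values[i]
        for j, d2 in enumerate(drugs):
            if i == j or row[j] < theta:
                continue
            for ph in phenotypes:
                if (d2, ph) not in known.pairs:
                    candidates.add((d2, ph))
    return candidates


def candidate_enrichment(
    candidates: set[tuple[str, str]],
    reference: AssociationSet,
    drugs: list[str] | set[str],
    phenotypes: list[str] | set[str],
    known: AssociationSet,
    include_known: bool = False,
) -> EnrichmentResult:
    """One-tailed enrichment of candidate pairs in the reference set.

    The universe is the drug-roster x phenotype-vocabulary cross product,
    minus known pairs (candidates exclude them by construction; keeping them
    would distort the margins).  ``include_known=True`` keeps them instead.
    """
    if not candidates:
        raise UntestableThresholdError("no candidate pairs at this threshold")
    drugs = set(drugs)
    phenotypes = set(phenotypes)
    space = {(d, p) for d in drugs for p in phenotypes}
    if not space:
        raise ValueError("empty association universe")
    universe = space if include_known else space - known.pairs
    bad = candidates & known.pairs
    if bad:
        raise ValueError(f"{len(bad)} candidates overlap the known set")
    query = candidates & universe
    if len(query) != len(candidates):
        log.debug(
            "candidate_enrichment: %d candidates outside the universe dropped",
            len(candidates) - len(query),
        )
    if not query:
        raise UntestableThresholdError("all candidates fall outside the universe")
    ref = reference.pairs & universe
    return overlap_enrichment(query, ref, universe)


def select_threshold(
    sim: SimilarityMatrix,
    known: AssociationSet,
    reference: AssociationSet,
    drugs: list[str],
    phenotypes: list[str] | set[str],
    grid: list[float] | None = None,
    include_known: bool = False,
) -> ThresholdScan:
    """Scan the grid and choose the threshold with the lowest enrichment p.

    Untestable thresholds (empty candidate sets) are recorded with p None and
    skipped.  Ties at the minimal p go to the LARGEST threshold (fewer,
    higher-confidence candidates).
    """
    if grid is None:
        grid = default_grid()
    if not grid:
        raise ValueError("threshold grid must be non-empty")
    if sorted(grid) != list(grid):
        raise ValueError("threshold grid must be sorted ascending")
    scan = ThresholdScan(measure=sim.measure, grid=list(grid))
    for theta in grid:
        candidates = transfer_associations(sim, known, theta)
        scan.candidate_count_at.append(len(candidates))
        if not candidates:
            scan.p_at.append(None)
            continue
        try:
            result = candidate_enrichment(
                candidates, reference, sim.drugs, phenotypes, known, include_known
            )
        except UntestableThresholdError:
            scan.p_at.append(None)
            continue
        scan.p_at.append(result.p_value)
    testable = [(p, theta) for p, theta in zip(scan.p_at, grid) if p is not None]
    if not testable:
        raise UntestableThresholdError("no testable threshold in the grid")
    best_p = min(p for p, _ in testable)
    scan.chosen = max(theta for p, theta in testable if p == best_p)
    return scan


def predict_intersection(
    per_measure: dict[str, set[tuple[str, str]]],
    thresholds: dict[str, float],
) -> PredictionSet:
    """Pairs proposed by all three measures at their chosen thresholds."""
    missing = set(MEASURES) - set(per_measure)
    if missing:
        raise ValueError(f"missing candidate sets for measures: {sorted(missing)}")
    pairs = set.intersection(*(per_measure[m] for m in MEASURES))
    return PredictionSet(
        pairs=pairs,
        per_measure_sets={m: set(per_measure[m]) for m in MEASURES},
        thresholds=dict(thresholds),
    )


def predict_associations(
    sims: dict[str, SimilarityMatrix],
    known: AssociationSet,
    reference: AssociationSet,
    phenotypes: list[str] | set[str],
    grid: list[float] | None = None,
    include_known: bool = False,
) -> tuple[PredictionSet, dict[str, ThresholdScan]]:
    """Full prediction pass: per-measure threshold selection, transfer at the
    chosen thresholds, then the conservative three-way intersection."""
    missing = set(MEASURES) - set(sims)
    if missing:
        raise ValueError(f"missing similarity matrices for measures: {sorted(missing)}")
    scans: dict[str, ThresholdScan] = {}
    per_measure: dict[str, set[tuple[str, str]]] = {}
    for m in MEASURES:
        scan = select_threshold(
            sims[m], known, reference, sims[m].drugs, phenotypes, grid, include_known
        )
        scans[m] = scan
        per_measure[m] = transfer_associations(sims[m], known, scan.chosen)
    prediction = predict_intersection(
        per_measure, {m: scans[m].chosen for m in MEASURES}
    )
    return prediction, scans


# ---------------------------------------------------------------------------
# evaluation helpers


def precision_recall(
    predicted: set[tuple[str, str]], truth: set[tuple[str, str]]
) -> tuple[float, float]:
    """Precision and recall of a predicted pair set against a truth set.

    Empty predictions give precision 0 (nothing asserted, nothing right);
    empty truth gives recall 0.
    """
    hits = len(predicted & truth)
    precision = hits / len(predicted) if predicted else 0.0
    recall = hits / len(truth) if truth else 0.0
    return precision, recall


def harmonic_f1(precision: float, recall: float) -> float:
    """F1 as the harmonic mean of precision and recall."""
    if precision < 0 or recall < 0:
        raise ValueError("precision and recall must be non-negative")
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)
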