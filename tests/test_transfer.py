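"""Association transfer, threshold selection and intersection predictions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drugpath.errors import UntestableThresholdError
from drugpath.io import AssociationSet
from drugpath.similarity import SimilarityMatrix
from drugpath.transfer import (
    candidate_enrichment,
    default_grid,
    harmonic_f1,
    precision_recall,
    predict_intersection,
    select_threshold,
    transfer_associations,
)
from oracles import hypergeom_tail_exact


def sim_matrix(drugs, pairs):
    """Symmetric matrix with given off-diagonal similarities (default 0)."""
    n = len(drugs)
    vals = np.eye(n)
    idx = {d: i for i, d in enumerate(drugs)}
    for (d1, d2), v in pairs.items():
        vals[idx[d1], idx[d2]] = vals[idx[d2], idx[d1]] = v
    return SimilarityMatrix(drugs=list(drugs), values=vals, measure="gene")


class TestTransferAssociations:
    def test_transfers_above_threshold(self):
        sim = sim_matrix(["d1", "d2"], {("d1", "d2"): 0.9})
        known = AssociationSet({("d1", "I")}, "indication")
        assert transfer_associations(sim, known, 0.5) == {("d2", "I")}

    def test_known_pairs_removed(self):
        sim = sim_matrix(["d1", "d2"], {("d1", "d2"): 0.9})
        known = AssociationSet({("d1", "I"), ("d2", "I")}, "indication")
        assert transfer_associations(sim, known, 0.5) == set()

    def test_high_threshold_yields_nothing(self):
        sim = sim_matrix(["d1", "d2"], {("d1", "d2"): 0.4})
        known = AssociationSet({("d1", "I")}, "indication")
        assert transfer_associations(sim, known, 0.41) == set()

    def test_bidirectional(self):
        sim = sim_matrix(["d1", "d2"], {("d1", "d2"): 0.8})
        known = AssociationSet({("d1", "A"), ("d2", "B")}, "indication")
        assert transfer_associations(sim, known, 0.5) == {("d2", "A"), ("d1", "B")}

    @given(
        theta1=st.floats(0, 1), theta2=st.floats(0, 1),
        s=st.floats(0, 1, allow_nan=False),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_candidates_anti_monotone_in_threshold(self, theta1, theta2, s):
        lo, hi = sorted((theta1, theta2))
        sim = sim_matrix(["d1", "d2", "d3"], {("d1", "d2"): s, ("d2", "d3"): s / 2})
        known = AssociationSet({("d1", "I"), ("d3", "J")}, "indication")
        assert transfer_associations(sim, known, hi) <= transfer_associations(sim, known, lo)


class TestCandidateEnrichment:
    def test_toy_universe_matches_enumeration(self):
        # 2 drugs x 2 phenotypes, no known pairs: universe of 4 cells
        known = AssociationSet(set(), "indication")
        reference = AssociationSet({("d1", "p1")}, "indication")
        candidates = {("d1", "p1"), ("d2", "p2")}
        res = candidate_enrichment(candidates, reference, ["d1", "d2"], ["p1", "p2"], known)
        expected = float(hypergeom_tail_exact(4, 1, 2, 1))
        assert res.p_value == pytest.approx(expected, rel=1e-12)

    def test_empty_candidates_untestable(self):
        known = AssociationSet(set(), "indication")
        reference = AssociationSet({("d1", "p1")}, "indication")
        with pytest.raises(UntestableThresholdError):
            candidate_enrichment(set(), reference, ["d1"], ["p1"], known)

    def test_reference_covering_universe_gives_p_one(self):
        known = AssociationSet(set(), "indication")
        drugs, phenos = ["d1", "d2"], ["p1", "p2"]
        reference = AssociationSet({(d, p) for d in drugs for p in phenos}, "indication")
        res = candidate_enrichment({("d1", "p2")}, reference, drugs, phenos, known)
        assert res.p_value == 1.0

    def test_known_pairs_excluded_from_universe(self):
        known = AssociationSet({("d1", "p1")}, "indication")
        reference = AssociationSet({("d2", "p2")}, "indication")
        res = candidate_enrichment({("d2", "p2")}, reference, ["d1", "d2"], ["p1", "p2"], known)
        # universe is 3 cells once the known pair is removed
        assert res.table.total == 3

    def test_candidate_overlapping_known_rejected(self):
        known = AssociationSet({("d1", "p1")}, "indication")
        reference = AssociationSet(set(), "indication")
        with pytest.raises(ValueError, match="overlap"):
            candidate_enrichment({("d1", "p1")}, reference, ["d1"], ["p1", "p2"], known)


class TestSelectThreshold:
    def _setup(self):
        # planted structure: d1~d2 strongly similar and share reference
        # phenotypes; d3 weakly similar to both
        drugs = ["d1", "d2", "d3"]
        sim = sim_matrix(drugs, {("d1", "d2"): 0.8, ("d1", "d3"): 0.3, ("d2", "d3"): 0.3})
        known = AssociationSet({("d1", "A"), ("d2", "B"), ("d3", "C")}, "indication")
        reference = AssociationSet({("d2", "A"), ("d1", "B")}, "indication")
        phenotypes = ["A", "B", "C", "D"]
        return sim, known, reference, drugs, phenotypes

    def test_minimum_found_on_grid(self):
        sim, known, reference, drugs, phenotypes = self._setup()
        scan = select_threshold(sim, known, reference, drugs, phenotypes,
                                grid=[0.0, 0.2, 0.5, 0.9])
        # at 0.5 only the d1<->d2 transfers remain and both hit the reference
        assert scan.chosen == 0.5
        best = scan.p_at[scan.grid.index(0.5)]
        assert best == min(p for p in scan.p_at if p is not None)

    def test_tie_breaks_to_largest_threshold(self):
        sim, known, reference, drugs, phenotypes = self._setup()
        # 0.4 and 0.5 give identical candidate sets, hence identical p
        scan = select_threshold(sim, known, reference, drugs, phenotypes,
                                grid=[0.4, 0.5])
        assert scan.chosen == 0.5

    def test_untestable_thresholds_recorded_and_skipped(self):
        sim, known, reference, drugs, phenotypes = self._setup()
        scan = select_threshold(sim, known, reference, drugs, phenotypes,
                                grid=[0.5, 0.95])
        assert scan.p_at[1] is None and scan.chosen == 0.5

    def test_all_untestable_errors(self):
        sim, known, reference, drugs, phenotypes = self._setup()
        with pytest.raises(UntestableThresholdError):
            select_threshold(sim, known, reference, drugs, phenotypes, grid=[0.95])

    def test_single_zero_grid(self):
        sim, known, reference, drugs, phenotypes = self._setup()
        scan = select_threshold(sim, known, reference, drugs, phenotypes, grid=[0.0])
        assert scan.chosen == 0.0

    def test_default_grid_shape(self):
        g = default_grid()
        assert g[0] == 0.0 and g[-1] == 1.0 and len(g) == 101


class TestPredictIntersection:
    def test_common_pair_only(self):
        per = {
            "gene": {("d", "p"), ("d", "q")},
            "go": {("d", "p"), ("e", "q")},
            "kegg": {("d", "p")},
        }
        pred = predict_intersection(per, {"gene": 0.5, "go": 0.4, "kegg": 0.3})
        assert pred.pairs == {("d", "p")}

    def test_any_empty_set_empties_result(self):
        per = {"gene": {("d", "p")}, "go": set(), "kegg": {("d", "p")}}
        assert predict_intersection(per, {}).pairs == set()

    def test_missing_measure_errors(self):
        with pytest.raises(ValueError, match="kegg"):
            predict_intersection({"gene": set(), "go": set()}, {})


class TestEvaluationHelpers:
    @pytest.mark.parametrize(
        "precision,recall,expected",
        [(0.34, 0.56, 0.42), (0.36, 0.24, 0.29)],
    )
    def test_harmonic_f1_rounds_to_reported_values(self, precision, recall, expected):
        assert round(harmonic_f1(precision, recall), 2) == pytest.approx(expected, abs=0.005)

    def test_precision_recall_edge_cases(self):
        assert precision_recall(set(), {("a", "b")}) == (0.0, 0.0)
        assert precision_recall({("a", "b")}, set()) == (0.0, 0.0)
        p, r = precision_recall({("a", "b"), ("c", "d")}, {("a", "b")})
        assert (p, r) == (0.5, 1.0)
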