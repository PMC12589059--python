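import logging

import pytest

from ddsn.errors import InconsistencyError, ParameterError
from ddsn.io_formats import DrugAnnotation
from ddsn.labeling import (
    Histogram,
    accuracy_summary,
    build_cluster_report,
    classify_cluster,
    dominant_code,
    level_histogram,
    nearest_int,
    round1,
    targets_for_codes,
    top_level4,
)
from helpers import TABLE2_ROWS


def ann(**codes_by_drug):
    return {
        drug: DrugAnnotation(drug, frozenset(codes))
        for drug, codes in codes_by_drug.items()
    }


class TestLevelHistogram:
    def test_level1_distinct_per_drug(self):
        annotations = ann(d1={"N"}, d2={"N", "C"}, d3=set())
        h = level_histogram({"d1", "d2", "d3"}, annotations, level=1)
        assert h.counts == {"N": 2, "C": 1}

    def test_same_prefix_counts_once(self):
        annotations = ann(d1={"N05BA", "N05CB"})
        h = level_histogram({"d1"}, annotations, level=2)
        assert h.counts == {"N05": 1}

    def test_empty_annotations(self):
        assert level_histogram({"d1"}, {}, level=1).counts == {}

    def test_restriction_to_label(self):
        annotations = ann(d1={"N05CB", "C07AB"}, d2={"C01AA"})
        h = level_histogram({"d1", "d2"}, annotations, level=2, restrict_to_label="N")
        assert h.counts == {"N05": 1}

    def test_short_codes_skip_deeper_levels(self):
        annotations = ann(d1={"N"})
        assert level_histogram({"d1"}, annotations, level=4).counts == {}

    def test_invalid_level(self):
        with pytest.raises(ParameterError):
            level_histogram({"d1"}, {}, level=5)

    def test_level1_conservation(self):
        annotations = ann(
            d1={"N05CB", "N03AX"}, d2={"C07AB", "L01EM"}, d3={"B01AC"}, d4=set()
        )
        h = level_histogram(set(annotations), annotations, level=1)
        expected_total = sum(
            len({c[0] for c in a.atc_codes}) for a in annotations.values()
        )
        assert sum(h.counts.values()) == expected_total


class TestDominantCode:
    def test_max_count_wins(self):
        # pattern of an antineoplastic-dominated community of 51 drugs
        assert dominant_code(Histogram(1, {"L": 31, "B": 5, "J": 4})) == "L"

    def test_tie_is_lexicographic_and_logged(self, caplog):
        with caplog.at_level(logging.WARNING, logger="ddsn.labeling"):
            assert dominant_code(Histogram(1, {"N": 2, "C": 2})) == "C"
        assert "tie" in caplog.text

    def test_singleton(self):
        assert dominant_code(Histogram(1, {"N": 1})) == "N"

    def test_empty_histogram_rejected(self):
        with pytest.raises(ParameterError):
            dominant_code(Histogram(1, {}))

    def test_dominance_invariant(self):
        h = Histogram(1, {"L": 31, "B": 5, "J": 4})
        assert all(h.counts[dominant_code(h)] >= v for v in h.counts.values())


class TestClassifyCluster:
    def test_foreign_code_is_candidate(self):
        # an antibacterial drug inside an antineoplastic-labeled community
        annotations = ann(chloramphenicol={"J01BA"}, other={"L01EM"})
        matched, candidates = classify_cluster(set(annotations), annotations, "L")
        assert "chloramphenicol" in candidates
        assert "other" in matched

    def test_any_matching_code_suffices(self):
        annotations = ann(d1={"L01EL", "B01AC"})
        matched, _ = classify_cluster({"d1"}, annotations, "L")
        assert matched == {"d1"}

    def test_codeless_drug_is_candidate(self):
        annotations = ann(d1=set())
        matched, candidates = classify_cluster({"d1", "d2"}, annotations, "L")
        assert matched == frozenset()
        assert candidates == {"d1", "d2"}

    def test_partition_property(self):
        annotations = ann(a={"L01EM"}, b={"N05CB"}, c=set())
        cluster = {"a", "b", "c"}
        matched, candidates = classify_cluster(cluster, annotations, "L")
        assert matched | candidates == cluster
        assert not matched & candidates

    def test_label_validated(self):
        with pytest.raises(ParameterError):
            classify_cluster(set(), {}, "L01")


class TestAccuracySummary:
    def test_reference_totals(self):
        """The 12 reference rows aggregate to 53.4 / 20.2 / 73.6 / 26.4."""
        s = accuracy_summary(TABLE2_ROWS)
        assert s.weighted_pct_predominant == 53.4
        assert s.weighted_pct_confirmed == 20.2
        assert s.total_accuracy == 73.6
        assert s.pct_candidates == 26.4

    @pytest.mark.parametrize(
        "row,expected_accuracy",
        [
            ((6, 51, 60.8, 23.5), 84.3),
            ((10, 24, 87.5, 4.2), 91.7),
        ],
    )
    def test_per_row_accuracy(self, row, expected_accuracy):
        s = accuracy_summary([row])
        assert s.rows[0].pct_accuracy == expected_accuracy

    def test_saturated_row(self):
        s = accuracy_summary([(1, 10, 100.0, 0.0)])
        assert (
            s.weighted_pct_predominant,
            s.weighted_pct_confirmed,
            s.total_accuracy,
            s.pct_candidates,
        ) == (100.0, 0.0, 100.0, 0.0)

    def test_accuracy_at_least_predominant(self):
        for row in TABLE2_ROWS:
            s = accuracy_summary([row])
            assert s.rows[0].pct_accuracy >= s.rows[0].pct_predominant

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(InconsistencyError):
            accuracy_summary([(1, 10, 90.0, 20.0)])

    def test_bad_inputs_rejected(self):
        with pytest.raises(ParameterError):
            accuracy_summary([(1, 0, 50.0, 0.0)])
        with pytest.raises(ParameterError):
            accuracy_summary([(1, 10, 120.0, 0.0)])


class TestRounding:
    @pytest.mark.parametrize(
        "x,expected", [(84.31, 84.3), (91.666, 91.7), (0.05, 0.1), (53.445, 53.4)]
    )
    def test_round1_half_away(self, x, expected):
        assert round1(x) == expected

    @pytest.mark.parametrize("x,expected", [(31.008, 31), (0.5, 1), (1.499, 1), (20.5, 21)])
    def test_nearest_int(self, x, expected):
        assert nearest_int(x) == expected


class TestTopLevel4:
    def test_tie_expansion(self):
        # the antineoplastic community pattern: counts 8, 5, 5, 3, 3 at k=3
        drugs = {}
        spec = [("L04AA", 8), ("L01FX", 5), ("L01XX", 5), ("L01EM", 3), ("L01EL", 3)]
        i = 0
        for code, n in spec:
            for _ in range(n):
                drugs[f"d{i}"] = DrugAnnotation(f"d{i}", frozenset({code}))
                i += 1
        out = top_level4(set(drugs), drugs, "L", k=3)
        assert out == ("L04AA", "L01FX", "L01XX", "L01EL", "L01EM")

    def test_fewer_keys_than_k(self):
        annotations = ann(d1={"N05CB"}, d2={"N05CB"})
        assert top_level4({"d1", "d2"}, annotations, "N", k=3) == ("N05CB",)

    def test_empty(self):
        assert top_level4({"d1"}, {}, "N", k=3) == ()

    def test_all_results_match_label(self):
        annotations = ann(d1={"L01EM", "N05CB"}, d2={"L04AA"})
        out = top_level4(set(annotations), annotations, "L", k=3)
        assert out and all(code.startswith("L") for code in out)


class TestTargets:
    def test_restriction(self):
        m = {"L01EM": frozenset({"PIK3CA", "PIK3CG", "PIK3CD"})}
        out = targets_for_codes(["L01EM"], m)
        assert out == m

    def test_unknown_code_empty_with_warning(self, caplog):
        with caplog.at_level(logging.WARNING, logger="ddsn.labeling"):
            out = targets_for_codes(["X99XX"], {})
        assert out == {"X99XX": frozenset()}
        assert "X99XX" in caplog.text

    def test_empty_codes(self):
        assert targets_for_codes([], {"L01EM": frozenset({"t"})}) == {}


class TestClusterReport:
    def test_full_walkthrough(self):
        annotations = ann(
            a={"L01EM"}, b={"L01EM"}, c={"L04AA"}, d={"J01BA"}, e=set()
        )
        rep = build_cluster_report(
            6, set(annotations), annotations, {"L01EM": frozenset({"PIK3CA"})}
        )
        assert rep.label == "L"
        assert rep.matched_drugs == {"a", "b", "c"}
        assert rep.candidate_drugs == {"d", "e"}
        assert rep.pct_predominant == 60.0
        assert rep.top_level4 == ("L01EM", "L04AA")
        assert rep.targets["L01EM"] == {"PIK3CA"}
        assert rep.targets["L04AA"] == frozenset()

    def test_codeless_cluster_unlabeled(self):
        rep = build_cluster_report(1, {"x", "y"}, {}, {})
        assert rep.label is None
        assert rep.candidate_drugs == {"x", "y"}
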