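"""Domain matching, boundary agreement, aggregation, annotation I/O."""

import pytest

from tmcascade.evaluation import (
    EvaluationReport,
    ReferenceAnnotation,
    aggregate_reports,
    match_domains,
    read_annotations,
    write_annotations,
)
from tmcascade.segmentation import Segment

REF7 = ReferenceAnnotation(
    protein_id="p",
    tmds=((10, 30), (45, 65), (80, 100), (120, 140), (160, 180), (200, 220), (240, 260)),
)


class TestMatchDomains:
    def test_identity_prediction_scores_perfectly(self):
        rep = match_domains(list(REF7.tmds), REF7, tolerance=0)
        assert rep.n_resolved == rep.n_revealed == rep.n_ref_tmds == 7
        assert rep.n_boundaries_ok == rep.n_boundaries == 14
        assert all(m.dev_start == m.dev_end == 0 for m in rep.per_domain)

    def test_merged_prediction_resolves_neither_but_reveals_one(self):
        ref = ReferenceAnnotation("p", ((91, 113), (130, 151)))
        rep = match_domains([(89, 151)], ref)
        assert rep.n_resolved == 0
        assert rep.n_revealed == 1
        assert rep.n_boundaries_ok == 0
        assert all(m.shared for m in rep.per_domain)

    def test_uniform_shift_keeps_overlap_loses_boundaries(self):
        shifted = [(a + 10, b + 10) for a, b in REF7.tmds]
        rep = match_domains(shifted, REF7, tolerance=6)
        assert rep.n_resolved == 7
        assert rep.n_boundaries_ok == 0

    def test_boundaries_of_unresolved_domains_count_as_failures(self):
        ref = ReferenceAnnotation("p", ((10, 30), (50, 70)))
        rep = match_domains([(8, 72)], ref)  # merges both
        assert rep.n_boundaries == 4
        assert rep.n_boundaries_ok == 0

    def test_unmatched_reference_counts_unresolved(self):
        rep = match_domains([(10, 30)], ReferenceAnnotation("p", ((10, 30), (200, 220))))
        assert rep.n_resolved == 1
        assert rep.per_domain[1].pred_start is None

    def test_tmd_kind_filter_on_segment_input(self):
        segs = [Segment(1, 12, kind="signal_peptide"), Segment(10 + 0, 30, kind="tmd")]
        # SP segment is ignored even though it overlaps nothing
        rep = match_domains(segs, ReferenceAnnotation("p", ((10, 30),)))
        assert rep.n_resolved == 1

    def test_mismatched_protein_ids_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            match_domains([(10, 30)], REF7, protein_id="other")

    def test_tolerance_monotonicity(self):
        shifted = [(a + 4, b + 8) for a, b in REF7.tmds]
        counts = [
            match_domains(shifted, REF7, tolerance=t).n_boundaries_ok
            for t in range(0, 12)
        ]
        assert counts == sorted(counts)
        assert counts[0] == 0 and counts[-1] == 14

    def test_verdict_conservation(self):
        shifted = [(a + 5, b + 7) for a, b in REF7.tmds]
        rep = match_domains(shifted, REF7)
        assert sum(2 for _ in rep.per_domain) == rep.n_boundaries


class TestAggregate:
    def _report(self, n_ref, n_res, n_ok):
        return EvaluationReport(
            protein_id="x",
            tolerance=6,
            n_ref_tmds=n_ref,
            n_resolved=n_res,
            n_revealed=n_res,
            n_boundaries=2 * n_ref,
            n_boundaries_ok=n_ok,
        )

    def test_perfect_single_report(self):
        s = aggregate_reports([self._report(7, 7, 14)])
        assert s.pct_resolved == 100.0 and s.pct_boundaries == 100

    def test_rounding_to_published_precision(self):
        s = aggregate_reports([self._report(35, 34, 62)])
        assert s.pct_resolved == 97.1  # printed as "97%"
        assert s.pct_boundaries == 89
        s = aggregate_reports([self._report(140, 139, 236)])
        assert s.pct_resolved == 99.3
        assert s.pct_boundaries == 84

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            aggregate_reports([])

    def test_mixed_tolerances_rejected(self):
        a = self._report(7, 7, 14)
        b = EvaluationReport("y", 3, 7, 7, 7, 14, 14)
        with pytest.raises(ValueError, match="mixed"):
            aggregate_reports([a, b])

    def test_self_evaluation_is_perfect_for_any_tolerance(self):
        for tol in (0, 3, 6, 10):
            rep = match_domains(list(REF7.tmds), REF7, tolerance=tol)
            s = aggregate_reports([rep])
            assert s.pct_resolved == 100.0 and s.pct_boundaries == 100


class TestAnnotationIO:
    def test_round_trip_with_signal_peptide(self, tmp_path):
        ann = ReferenceAnnotation(
            "P47871",
            tmds=((137, 161), (174, 198)),
            signal_peptide=(1, 25),
        )
        path = tmp_path / "ref.tsv"
        write_annotations([ann, REF7], path)
        back = read_annotations(path)
        assert back["P47871"].tmds == ann.tmds
        assert back["P47871"].signal_peptide == (1, 25)
        assert back["p"].tmds == REF7.tmds

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("protein_id\tstart\n x\t1\n")
        with pytest.raises(ValueError, match="lacks columns"):
            read_annotations(path)

    def test_overlapping_reference_intervals_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ReferenceAnnotation("p", ((10, 30), (25, 40)))
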