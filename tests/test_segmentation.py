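"""Level-crossing segmentation, classification, merged-domain splitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmcascade.scales import ProteinSequence
from tmcascade.segmentation import (
    Segment,
    SegmentationParams,
    apply_splitting,
    classify_segments,
    detect_segments,
    predict_topography,
    split_merged_segment,
)
from tmcascade.synthetic import (
    BlockArchitecture,
    generate_block_protein,
)


class TestDetect:
    @pytest.mark.parametrize(
        "values, u, expected",
        [
            ([0, 1, 1, 0], 0.5, [(2, 3)]),
            ([1, 0, 1], 0.5, [(1, 1), (3, 3)]),
            ([0.5], 0.5, []),  # tie counts as below
            ([1, 1, 1], 0.0, [(1, 3)]),
            ([0, 0], 0.5, []),
        ],
    )
    def test_runs_above_level(self, values, u, expected):
        segs = detect_segments(np.asarray(values, float), u)
        assert [s.as_tuple() for s in segs] == expected

    def test_detected_positions_equal_strict_exceedance_set(self, rng):
        values = rng.normal(size=200)
        u = float(np.median(values))
        segs = detect_segments(values, u)
        covered = {k for s in segs for k in range(s.start, s.end + 1)}
        assert covered == {k + 1 for k in range(200) if values[k] > u}

    def test_raising_u_never_enlarges_coverage(self, rng):
        values = rng.normal(size=300)
        prev_cover = None
        for u in np.quantile(values, [0.1, 0.3, 0.5, 0.7, 0.9]):
            segs = detect_segments(values, float(u))
            cover = {k for s in segs for k in range(s.start, s.end + 1)}
            if prev_cover is not None:
                assert cover <= prev_cover
            prev_cover = cover


class TestClassify:
    def test_narrow_n_terminal_peak_is_signal_peptide(self):
        segs = classify_segments([Segment(11, 23)], seq_length=477)
        assert segs[0].kind == "signal_peptide"

    def test_long_segment_is_tmd(self):
        segs = classify_segments([Segment(143, 166)], seq_length=477)
        assert segs[0].kind == "tmd"

    def test_short_interior_segment_is_hydrophobic_region(self):
        segs = classify_segments([Segment(100, 105)], seq_length=477)
        assert segs[0].kind == "hydrophobic_region"

    def test_overlapping_input_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            classify_segments([Segment(10, 40), Segment(30, 60)], seq_length=100)

    def test_segment_past_sequence_end_rejected(self):
        with pytest.raises(ValueError, match="past sequence length"):
            classify_segments([Segment(90, 110)], seq_length=100)


class TestSplit:
    @pytest.mark.parametrize(
        "merged, expected",
        [
            ((89, 151), ((89, 109), (131, 151))),
            ((246, 312), ((246, 266), (292, 312))),
        ],
    )
    def test_outer_boundary_splitting(self, merged, expected):
        left, right = split_merged_segment(Segment(*merged, kind="tmd"), 20)
        assert (left.as_tuple(), right.as_tuple()) == expected
        assert left.kind == right.kind == "tmd"
        assert left.source == right.source == "split"

    def test_children_contained_and_sized(self):
        parent = Segment(50, 120, kind="tmd")
        left, right = split_merged_segment(parent, 20)
        assert parent.start <= left.start <= left.end <= parent.end
        assert parent.start <= right.start <= right.end <= parent.end
        assert left.length == right.length == 21
        assert left.end < right.start

    def test_too_narrow_segment_unsplittable(self):
        with pytest.raises(ValueError, match="cannot be split"):
            split_merged_segment(Segment(10, 40), 20)

    def test_apply_splitting_only_touches_wide_tmds(self):
        segs = [
            Segment(5, 20, kind="signal_peptide"),
            Segment(89, 151, kind="tmd"),
            Segment(200, 225, kind="tmd"),
        ]
        out = apply_splitting(segs, SegmentationParams(split_enabled=True))
        assert [s.as_tuple() for s in out] == [(5, 20), (89, 109), (131, 151), (200, 225)]


class TestPredictTopography:
    def test_noiseless_blocks_recovered_one_to_one(self):
        arch = BlockArchitecture(
            blocks=(("loop", 20), ("tmd", 22), ("loop", 18), ("tmd", 25), ("loop", 20)),
            noise_p=0.0,
            seed=7,
        )
        seq, ann = generate_block_protein(arch)
        pred = predict_topography(seq, "H3", 4)
        tmds = pred.tmds()
        assert len(tmds) == len(ann.tmds) == 2
        for seg, (a, b) in zip(tmds, ann.tmds):
            assert abs(seg.start - a) <= 5 and abs(seg.end - b) <= 5

    def test_all_hydrophilic_sequence_yields_no_tmds(self):
        pred = predict_topography("DEKR" * 30, "H3", 4)
        assert pred.tmds() == ()

    def test_segments_sorted_disjoint_within_bounds(self):
        arch = BlockArchitecture(
            blocks=tuple(("tmd", 20) if i % 2 else ("loop", 17) for i in range(9)),
            noise_p=0.1,
            seed=3,
        )
        seq, _ = generate_block_protein(arch)
        pred = predict_topography(seq, "H3", 4)
        segs = pred.segments
        assert all(1 <= s.start <= s.end <= seq.length for s in segs)
        assert all(a.end < b.start for a, b in zip(segs, segs[1:]))

    def test_deterministic_for_fixed_inputs(self):
        seq = ProteinSequence("p", "DDDD" + "LIVF" * 6 + "DDDDDD")
        a = predict_topography(seq, "H2", 4)
        b = predict_topography(seq, "H2", 4)
        assert a == b

    def test_constant_level_override(self):
        seq = ProteinSequence("p", "D" * 20 + "L" * 20 + "D" * 20)
        pred = predict_topography(seq, "H3", 4, level=0.9)
        # raw values are -1/+1; a level of 0.9 survives only deep inside the block
        assert all(s.start > 20 and s.end <= 40 for s in pred.segments)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(u_lo=st.floats(-0.5, 0.0), du=st.floats(0.01, 0.5), seed=st.integers(0, 100))
    def test_monotonicity_total_coverage_in_u(self, u_lo, du, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(size=120)
        lo = sum(s.length for s in detect_segments(values, u_lo))
        hi = sum(s.length for s in detect_segments(values, u_lo + du))
        assert hi <= lo
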