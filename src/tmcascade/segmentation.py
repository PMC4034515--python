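"""Level-crossing segmentation of smoothed hydrophobicity profiles.

A residue belongs to a hydrophobic segment when the smoothed profile lies
strictly above the threshold level, f_n(k) > u (a tie counts as below).
Maximal runs of such residues become candidate segments, which are then
classified by position and length:

* entirely within the first ``sp_window`` residues -> signal-peptide region
  (signal peptides show up as a narrow hydrophobic peak at the N-terminus);
* at least ``min_tmd_length`` residues long        -> transmembrane domain
  (TMD) candidate;
* otherwise                                         -> short hydrophobic region.

Two closely spaced helices occasionally merge into one long segment.  Such
a segment can be split from its outer boundaries using the assumed average
domain length L_avg (default 20 aa): the children are
``[start, start + L_avg]`` and ``[end - L_avg, end]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from tmcascade.cascade import CascadeConfig, HydroProfile, make_profile
from tmcascade.scales import ProteinSequence, encode_sequence

KINDS = ("tmd", "signal_peptide", "hydrophobic_region")


@dataclass(frozen=True)
class Segment:
    """A 1-based inclusive residue interval with a classification."""

    start: int
    end: int
    kind: str = "hydrophobic_region"
    source: str = "detected"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid interval ({self.start}, {self.end})")
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")

    @property
    def length(self) -> int:
        """Inclusive residue count."""
        return self.end - self.start + 1

    def as_tuple(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable thresholds for segment classification and splitting.

    min_tmd_length : minimum run length (residues) to call a TMD candidate;
        12 sits below the canonical 15-30 aa helix range but above spike
        width. sp_window : a segment entirely within the first this-many
        residues is flagged as a signal-peptide region.  l_avg : assumed
        average domain length used when splitting merged segments.
        split_enabled : opt-in splitting of merged TMD segments.
    """

    min_tmd_length: int = 12
    sp_window: int = 30
    l_avg: int = 20
    split_enabled: bool = False

    def __post_init__(self) -> None:
        if self.min_tmd_length < 1:
            raise ValueError("min_tmd_length must be >= 1")
        if self.l_avg < 1:
            raise ValueError("l_avg must be >= 1")
        if self.sp_window < 0:
            raise ValueError("sp_window must be >= 0")


@dataclass(frozen=True)
class Prediction:
    """End-to-end prediction result for one protein."""

    protein_id: str
    scale_name: str
    n: int
    level_u: float
    segments: tuple[Segment, ...]
    params: SegmentationParams = field(default_factory=SegmentationParams)

    def tmds(self) -> tuple[Segment, ...]:
        return tuple(s for s in self.segments if s.kind == "tmd")


def _check_sorted_disjoint(segments: Sequence[Segment]) -> None:
    for a, b in zip(segments, segments[1:]):
        if b.start <= a.end:
            raise ValueError(
                f"segments ({a.start},{a.end}) and ({b.start},{b.end}) "
                "overlap or are unsorted"
            )


def detect_segments(
    profile: HydroProfile | Sequence[float], u: float | None = None
) -> list[Segment]:
    """Maximal runs of positions with f_n(k) > u, as hydrophobic_region segments.

    ``u`` defaults to the profile's attached level.  The comparison is
    strict: f_n(k) == u counts as below the level.
    """
    if isinstance(profile, HydroProfile):
        values = profile.series
        if u is None:
            u = profile.level_u
    else:
        values = np.asarray(profile, dtype=float)
        if u is None:
            raise ValueError("u is required when passing a bare series")
    if values.size == 0:
        raise ValueError("profile is empty")

    above = values > u
    segments: list[Segment] = []
    start = None
    for k, flag in enumerate(above, start=1):
        if flag and start is None:
            start = k
        elif not flag and start is not None:
            segments.append(Segment(start, k - 1))
            start = None
    if start is not None:
        segments.append(Segment(start, len(values)))
    return segments


def classify_segments(
    segments: Sequence[Segment],
    seq_length: int,
    params: SegmentationParams | None = None,
) -> list[Segment]:
    """Assign kinds (signal_peptide / tmd / hydrophobic_region) by position and length."""
    params = params or SegmentationParams()
    segments = sorted(segments, key=lambda s: s.start)
    _check_sorted_disjoint(segments)
    out: list[Segment] = []
    for seg in segments:
        if seg.end > seq_length:
            raise ValueError(
                f"segment ({seg.start},{seg.end}) extends past sequence length {seq_length}"
            )
        if seg.end <= params.sp_window:
            kind = "signal_peptide"
        elif seg.length >= params.min_tmd_length:
            kind = "tmd"
        else:
            kind = "hydrophobic_region"
        out.append(replace(seg, kind=kind))
    return out


def split_merged_segment(segment: Segment, l_avg: int = 20) -> tuple[Segment, Segment]:
    """Split a merged two-helix segment from its outer boundaries.

    Children are ``[start, start + l_avg]`` and ``[end - l_avg, end]``
    (each ``l_avg + 1`` residues); they must not overlap, which requires
    ``end - start >= 2*l_avg + 2``.
    """
    if segment.end - segment.start < 2 * l_avg + 2:
        raise ValueError(
            f"segment ({segment.start},{segment.end}) of width "
            f"{segment.end - segment.start} cannot be split with l_avg={l_avg} "
            f"(needs width >= {2 * l_avg + 2})"
        )
    left = Segment(segment.start, segment.start + l_avg, kind="tmd", source="split")
    right = Segment(segment.end - l_avg, segment.end, kind="tmd", source="split")
    return left, right


def apply_splitting(
    segments: Iterable[Segment], params: SegmentationParams
) -> list[Segment]:
    """Replace every splittable merged TMD segment by its two children."""
    out: list[Segment] = []
    for seg in segments:
        if (
            seg.kind == "tmd"
            and seg.end - seg.start >= 2 * params.l_avg + 2
        ):
            out.extend(split_merged_segment(seg, params.l_avg))
        else:
            out.append(seg)
    return out


def predict_topography(
    seq: ProteinSequence | str,
    scale_name: str = "H3",
    n: int = 4,
    level: float | None = None,
    params: SegmentationParams | None = None,
    edge_rule: str = "truncate",
    unknown_policy: str = "neutral-zero",
) -> Prediction:
    """Full pipeline: encode, cascade-smooth, threshold, classify, optionally split.

    Parameters
    ----------
    seq
        Protein sequence (object or residue string).
    scale_name
        Hydrophobicity scale identifier (H1..H7).
    n
        Cascade depth (final window width 2n+1).
    level
        Constant threshold u; default is the whole-chain mean of the raw
        series f_0.
    params
        Segmentation thresholds; splitting of merged segments is applied
        only when ``params.split_enabled``.
    """
    if isinstance(seq, str):
        seq = ProteinSequence(id="<anonymous>", residues=seq)
    params = params or SegmentationParams()
    f0 = encode_sequence(seq, scale_name, unknown_policy=unknown_policy)
    profile = make_profile(
        f0,
        protein_id=seq.id,
        scale_name=scale_name,
        config=CascadeConfig(n_max=n, edge_rule=edge_rule),
        level=level,
    )
    segments = classify_segments(detect_segments(profile), seq.length, params)
    if params.split_enabled:
        segments = apply_splitting(segments, params)
    return Prediction(
        protein_id=seq.id,
        scale_name=scale_name,
        n=n,
        level_u=profile.level_u,
        segments=tuple(segments),
        params=params,
    )
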