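"""Scoring predicted transmembrane segments against reference annotations.

Two statistics are reported, mirroring how hydropathy predictions are
customarily benchmarked against curated (e.g. UniProt) annotations:

* the fraction of reference TMDs *resolved* by the prediction, and
* the fraction of TMD boundary positions agreeing within a tolerance
  Delta k_b <= 6 residues (about half the final smoothing window, the
  intrinsic boundary-detection error of the method).

Matching rule: each reference TMD is assigned the predicted segment with
maximal residue overlap (at least one residue).  A reference TMD is
*resolved* iff it has an assignee and that assignee is claimed by no other
reference TMD — a merged prediction spanning two true helices resolves
neither.  Because published tallies sometimes count a merged segment as
revealing one of its helices, the report also carries ``n_revealed``
(each assigned predicted segment counts once); both conventions are
reported side by side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from tmcascade.segmentation import Segment

DEFAULT_TOLERANCE = 6


@dataclass(frozen=True)
class ReferenceAnnotation:
    """Reference TMD intervals (1-based inclusive) for one protein."""

    protein_id: str
    tmds: tuple[tuple[int, int], ...]
    signal_peptide: tuple[int, int] | None = None
    source: str = ""

    def __post_init__(self) -> None:
        tmds = tuple((int(a), int(b)) for a, b in self.tmds)
        object.__setattr__(self, "tmds", tmds)
        for (a, b) in tmds:
            if a > b or a < 1:
                raise ValueError(f"invalid reference interval ({a}, {b})")
        for (a, b), (c, d) in zip(tmds, tmds[1:]):
            if c <= b:
                raise ValueError(
                    f"reference intervals ({a},{b}) and ({c},{d}) overlap or are unsorted"
                )


@dataclass
class DomainMatch:
    """Per-reference-TMD matching record."""

    ref_start: int
    ref_end: int
    pred_start: int | None
    pred_end: int | None
    resolved: bool
    shared: bool  # assignee also claimed by another reference TMD
    dev_start: int | None
    dev_end: int | None
    start_ok: bool
    end_ok: bool


@dataclass
class EvaluationReport:
    """Resolved-domain and boundary-agreement counts for one protein."""

    protein_id: str
    tolerance: int
    n_ref_tmds: int
    n_resolved: int
    n_revealed: int
    n_boundaries: int
    n_boundaries_ok: int
    per_domain: list[DomainMatch] = field(default_factory=list)

    def per_domain_table(self) -> pd.DataFrame:
        return pd.DataFrame([vars(m) for m in self.per_domain])


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def match_domains(
    predicted: Sequence[Segment] | Sequence[tuple[int, int]],
    reference: ReferenceAnnotation,
    tolerance: int = DEFAULT_TOLERANCE,
    protein_id: str | None = None,
) -> EvaluationReport:
    """Score predicted TMD segments against one protein's reference TMDs.

    ``predicted`` may be Segment objects (only kind ``tmd`` is used) or
    bare (start, end) tuples.  Boundaries of unresolved reference TMDs
    count as failures, so ``n_boundaries`` is always ``2 * n_ref_tmds``.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    preds: list[tuple[int, int]] = []
    for p in predicted:
        if isinstance(p, Segment):
            if p.kind == "tmd":
                preds.append(p.as_tuple())
        else:
            preds.append((int(p[0]), int(p[1])))
    if protein_id is not None and protein_id != reference.protein_id:
        raise ValueError(
            f"protein id mismatch: predictions are for {protein_id!r}, "
            f"reference is for {reference.protein_id!r}"
        )

    # best-overlap assignment; ties go to the earlier predicted segment
    assignee: list[int | None] = []
    for ref in reference.tmds:
        best, best_ov = None, 0
        for j, pred in enumerate(preds):
            ov = _overlap(ref, pred)
            if ov > best_ov:
                best, best_ov = j, ov
        assignee.append(best)

    claims = {j: assignee.count(j) for j in set(assignee) if j is not None}
    matches: list[DomainMatch] = []
    n_resolved = 0
    n_ok = 0
    for ref, j in zip(reference.tmds, assignee):
        if j is None:
            matches.append(
                DomainMatch(*ref, None, None, False, False, None, None, False, False)
            )
            continue
        pred = preds[j]
        shared = claims[j] > 1
        resolved = not shared
        dev_start = abs(pred[0] - ref[0])
        dev_end = abs(pred[1] - ref[1])
        start_ok = resolved and dev_start <= tolerance
        end_ok = resolved and dev_end <= tolerance
        n_resolved += resolved
        n_ok += start_ok + end_ok
        matches.append(
            DomainMatch(
                ref[0], ref[1], pred[0], pred[1],
                resolved, shared, dev_start, dev_end, start_ok, end_ok,
            )
        )

    n_revealed = len(claims)  # each assigned predicted segment counts once
    return EvaluationReport(
        protein_id=reference.protein_id,
        tolerance=tolerance,
        n_ref_tmds=len(reference.tmds),
        n_resolved=n_resolved,
        n_revealed=n_revealed,
        n_boundaries=2 * len(reference.tmds),
        n_boundaries_ok=n_ok,
        per_domain=matches,
    )


@dataclass
class Summary:
    """Aggregate counts and percentages over many proteins."""

    n_ref_tmds: int
    n_resolved: int
    n_revealed: int
    n_boundaries: int
    n_boundaries_ok: int
    tolerance: int

    @property
    def pct_resolved(self) -> float:
        """Resolution percentage (strict one-to-one rule), 1 decimal."""
        return round(100.0 * self.n_resolved / self.n_ref_tmds, 1)

    @property
    def pct_revealed(self) -> float:
        """Resolution percentage (shared-counts-once rule), 1 decimal."""
        return round(100.0 * self.n_revealed / self.n_ref_tmds, 1)

    @property
    def pct_boundaries(self) -> int:
        """Boundary-agreement percentage, nearest integer."""
        return round(100.0 * self.n_boundaries_ok / self.n_boundaries)


def aggregate_reports(reports: Iterable[EvaluationReport]) -> Summary:
    """Sum per-protein counts into one summary; tolerance must be uniform."""
    reports = list(reports)
    if not reports:
        raise ValueError("cannot aggregate an empty collection of reports")
    tolerances = {r.tolerance for r in reports}
    if len(tolerances) > 1:
        raise ValueError(f"mixed tolerances in reports: {sorted(tolerances)}")
    return Summary(
        n_ref_tmds=sum(r.n_ref_tmds for r in reports),
        n_resolved=sum(r.n_resolved for r in reports),
        n_revealed=sum(r.n_revealed for r in reports),
        n_boundaries=sum(r.n_boundaries for r in reports),
        n_boundaries_ok=sum(r.n_boundaries_ok for r in reports),
        tolerance=tolerances.pop(),
    )


# ---------------------------------------------------------------------------
# annotation file I/O

ANNOTATION_COLUMNS = ("protein_id", "index", "start", "end")


def read_annotations(path) -> dict[str, ReferenceAnnotation]:
    """Read reference annotations from a tab-separated file.

    Expected columns: ``protein_id  index  start  end`` (header required,
    ``#`` comment lines ignored).  ``index`` is the 1-based TMD ordinal;
    a row with index ``SP`` records the signal peptide.  Intervals are
    1-based inclusive.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"index": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation file {path} lacks columns: {sorted(missing)}")
    out: dict[str, ReferenceAnnotation] = {}
    for pid, grp in df.groupby("protein_id", sort=False):
        sp_rows = grp[grp["index"].str.upper() == "SP"]
        tmd_rows = grp[grp["index"].str.upper() != "SP"]
        tmd_rows = tmd_rows.sort_values("start")
        sp = None
        if len(sp_rows):
            r = sp_rows.iloc[0]
            sp = (int(r["start"]), int(r["end"]))
        out[pid] = ReferenceAnnotation(
            protein_id=str(pid),
            tmds=tuple(
                (int(r["start"]), int(r["end"])) for _, r in tmd_rows.iterrows()
            ),
            signal_peptide=sp,
        )
    return out


def write_annotations(annotations: Iterable[ReferenceAnnotation], path) -> None:
    """Write reference annotations in the tab-separated format read back by
    :func:`read_annotations`."""
    from tmcascade import __version__

    rows = []
    for ann in annotations:
        if ann.signal_peptide is not None:
            rows.append((ann.protein_id, "SP", *ann.signal_peptide))
        for i, (a, b) in enumerate(ann.tmds, start=1):
            rows.append((ann.protein_id, str(i), a, b))
    with open(path, "w") as fh:
        fh.write(f"# tmcascade v{__version__} reference annotations (1-based inclusive)\n")
        pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(fh, sep="\t", index=False)
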