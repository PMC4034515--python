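"""Bundled 25-protein GPCR boundary benchmark.

Ships two interval sets per protein: curated reference TMD boundaries
(UniProt-style annotations) and the boundary sets obtained with the
cascade sliding-window method at the per-protein scale / depth / level
reported in the literature.  Running the evaluation module over these sets
reproduces the published agreement statistics without any sequence
downloads:

* ``known5``  — 5 receptors of known structure, 35 reference TMDs;
* ``gpcr20``  — 20 receptors annotated by similarity, 140 reference TMDs.

The cascade sets keep merged two-helix runs unsplit (P41595 89-151,
P35414 246-312); pass ``split=True`` to apply outer-boundary splitting
with the default average domain length before matching.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from tmcascade.evaluation import (
    EvaluationReport,
    ReferenceAnnotation,
    Summary,
    aggregate_reports,
    match_domains,
)
from tmcascade.segmentation import Segment, SegmentationParams, apply_splitting

BENCHMARK_SETS = ("known5", "gpcr20")


def _data_path(name: str):
    return resources.files("tmcascade.data").joinpath(name)


def load_reference(benchmark_set: str | None = None) -> dict[str, ReferenceAnnotation]:
    """Reference annotations, keyed by protein id."""
    with resources.as_file(_data_path("gpcr_benchmark_reference.tsv")) as path:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"index": str})
    if benchmark_set is not None:
        df = df[df["set"] == benchmark_set]
    out: dict[str, ReferenceAnnotation] = {}
    for pid, grp in df.groupby("protein_id", sort=False):
        sp_rows = grp[grp["index"] == "SP"]
        tmd_rows = grp[grp["index"] != "SP"].sort_values("start")
        out[str(pid)] = ReferenceAnnotation(
            protein_id=str(pid),
            tmds=tuple((int(r.start), int(r.end)) for r in tmd_rows.itertuples()),
            signal_peptide=(
                (int(sp_rows.iloc[0]["start"]), int(sp_rows.iloc[0]["end"]))
                if len(sp_rows)
                else None
            ),
            source="curated benchmark annotation",
        )
    return out


def load_cascade_predictions(
    benchmark_set: str | None = None, variant: str = "primary"
) -> dict[str, list[Segment]]:
    """Cascade-method boundary sets (TMD segments only), keyed by protein id.

    ``variant="alt"`` substitutes the alternative published setting where
    one exists (falls back to primary otherwise).
    """
    with resources.as_file(_data_path("gpcr_benchmark_cascade.tsv")) as path:
        df = pd.read_csv(path, sep="\t", comment="#")
    if benchmark_set is not None:
        df = df[df["set"] == benchmark_set]
    df = df[df["kind"] == "tmd"]
    out: dict[str, list[Segment]] = {}
    for pid, grp in df.groupby("protein_id", sort=False):
        variants = set(grp["variant"])
        use = variant if variant in variants else "primary"
        rows = grp[grp["variant"] == use].sort_values("start")
        out[str(pid)] = [
            Segment(int(r.start), int(r.end), kind="tmd") for r in rows.itertuples()
        ]
    return out


def evaluate_benchmark(
    benchmark_set: str = "known5",
    tolerance: int = 6,
    split: bool = False,
    variant: str = "primary",
) -> tuple[Summary, list[EvaluationReport]]:
    """Match the cascade boundary sets against the reference annotations.

    Returns the aggregate summary and the per-protein reports.  With
    ``split=True`` merged runs wide enough for outer-boundary splitting
    (width >= 2*l_avg + 2) are split before matching.
    """
    refs = load_reference(benchmark_set)
    preds = load_cascade_predictions(benchmark_set, variant=variant)
    params = SegmentationParams(split_enabled=True)
    reports = []
    for pid, ref in refs.items():
        segments = preds[pid]
        if split:
            segments = apply_splitting(segments, params)
        reports.append(match_domains(segments, ref, tolerance=tolerance))
    return aggregate_reports(reports), reports
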