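#!/usr/bin/env python
"""Reproduce the GPCR boundary-benchmark statistics under every convention.

Usage:  python scripts/reproduce_benchmark.py [--with-sequences]

Prints, for both benchmark sets, the resolution and boundary-agreement
aggregates under the strict one-to-one matching rule and the
shared-counts-once ("revealed") rule, with and without outer-boundary
splitting of merged runs, for each shipped row variant.  With
``--with-sequences`` (after scripts/fetch_uniprot.py has staged FASTA
files) it additionally recomputes each protein's profile from sequence at
the benchmark's per-protein scale/depth/level and scores those fresh
predictions against the reference annotations.
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path

REPO_ROOT = Path(__file__).resolve().parent.parent
sys.path.insert(0, str(REPO_ROOT / "src"))

import pandas as pd

from tmcascade.benchmark import _data_path, evaluate_benchmark, load_reference
from tmcascade.evaluation import aggregate_reports, match_domains
from tmcascade.io import read_fasta
from tmcascade.segmentation import SegmentationParams, predict_topography

UNIPROT_DIR = REPO_ROOT / "data" / "uniprot"


def tabulated() -> None:
    print("== aggregates from the shipped boundary tables ==")
    for bset in ("known5", "gpcr20"):
        for variant in ("primary", "alt"):
            for split in (False, True):
                s, _ = evaluate_benchmark(bset, split=split, variant=variant)
                print(
                    f"{bset:7s} variant={variant:7s} split={str(split):5s} "
                    f"resolved {s.n_resolved:3d}/{s.n_ref_tmds} "
                    f"({s.pct_resolved:5.1f}%)  revealed {s.n_revealed:3d} "
                    f"({s.pct_revealed:5.1f}%)  boundaries "
                    f"{s.n_boundaries_ok:3d}/{s.n_boundaries} ({s.pct_boundaries}%)"
                )


def from_sequences(split: bool) -> None:
    with open(_data_path("gpcr_benchmark_cascade.tsv")) as fh:  # type: ignore[arg-type]
        df = pd.read_csv(fh, sep="\t", comment="#")
    settings = (
        df[df["variant"] == "primary"]
        .groupby("protein_id", sort=False)
        .first()[["scale", "n", "level", "level_is_mean"]]
    )
    refs = load_reference()
    reports = []
    missing = []
    for pid, row in settings.iterrows():
        fasta = UNIPROT_DIR / f"{pid}.fasta"
        if not fasta.exists():
            missing.append(pid)
            continue
        (seq,) = read_fasta(fasta)
        level = None if int(row["level_is_mean"]) else float(row["level"])
        pred = predict_topography(
            seq, str(row["scale"]), int(row["n"]), level=level,
            params=SegmentationParams(split_enabled=split),
        )
        reports.append(match_domains(pred.tmds(), refs[str(pid)], tolerance=6))
    if missing:
        print(f"  (skipped {len(missing)} proteins without local FASTA: {missing})")
    if reports:
        s = aggregate_reports(reports)
        print(
            f"  from-sequence split={split}: resolved {s.n_resolved}/{s.n_ref_tmds} "
            f"({s.pct_resolved:.1f}%), revealed {s.n_revealed} "
            f"({s.pct_revealed:.1f}%), boundaries {s.n_boundaries_ok}/"
            f"{s.n_boundaries} ({s.pct_boundaries}%)"
        )


def main() -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--with-sequences", action="store_true")
    args = parser.parse_args()
    tabulated()
    if args.with_sequences:
        print("== aggregates recomputed from sequence ==")
        for split in (False, True):
            from_sequences(split)
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
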