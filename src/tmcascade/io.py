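"""File formats: FASTA input, TSV/BED/GFF3 segment output, profile tables.

Coordinates are 1-based inclusive everywhere inside the package and in the
TSV/GFF3 outputs (the convention of residue-numbered annotation tables);
only BED output converts to 0-based half-open, at write time.  Every output
file starts with comment lines recording the tool version and the full
parameter set, so a result file is self-describing.
"""

from __future__ import annotations

import io as _stdio
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import pandas as pd
from Bio import SeqIO

from tmcascade import __version__
from tmcascade.cascade import HydroProfile
from tmcascade.scales import ProteinSequence
from tmcascade.segmentation import Prediction, Segment

_GFF3_TYPES = {
    "tmd": "Transmembrane_helix",
    "signal_peptide": "Signal_peptide",
    "hydrophobic_region": "Hydrophobic_region",
}


def read_fasta(path) -> list[ProteinSequence]:
    """Read a (possibly multi-record, line-wrapped) FASTA file.

    The id is the header token before the first whitespace; the remainder
    of the header line is kept as the description.  Sequences are
    upper-cased.  Raises ValueError with a line number on an empty file or
    on sequence data appearing before any ``>`` header.
    """
    path = Path(path)
    with open(path) as handle:
        lines = handle.readlines()
    first = next(
        ((i, ln) for i, ln in enumerate(lines, start=1) if ln.strip()), None
    )
    if first is None:
        raise ValueError(f"{path}: empty FASTA file")
    if not first[1].lstrip().startswith(">"):
        raise ValueError(
            f"{path}:{first[0]}: expected a '>' header line, "
            f"found sequence data or garbage"
        )
    records = list(SeqIO.parse(_stdio.StringIO("".join(lines)), "fasta"))
    out = []
    for rec in records:
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        out.append(
            ProteinSequence(id=rec.id, residues=str(rec.seq).upper(), description=desc)
        )
    return out


def write_fasta(sequences: Iterable[ProteinSequence], handle: TextIO, width: int = 60) -> None:
    for seq in sequences:
        header = f">{seq.id}"
        if seq.description:
            header += f" {seq.description}"
        handle.write(header + "\n")
        for i in range(0, len(seq.residues), width):
            handle.write(seq.residues[i : i + width] + "\n")


def _param_header(params: dict | None) -> list[str]:
    lines = [f"# tmcascade v{__version__}"]
    if params:
        lines.append(
            "# parameters: " + " ".join(f"{k}={v}" for k, v in params.items())
        )
    return lines


def write_segments_tsv(
    predictions: Sequence[Prediction], handle: TextIO, params: dict | None = None
) -> None:
    """Tab-separated segments: protein, start, end, kind, source, scale, n, u."""
    for line in _param_header(params):
        handle.write(line + "\n")
    handle.write("protein_id\tstart\tend\tkind\tsource\tscale\tn\tu\n")
    for pred in predictions:
        for seg in pred.segments:
            handle.write(
                f"{pred.protein_id}\t{seg.start}\t{seg.end}\t{seg.kind}\t"
                f"{seg.source}\t{pred.scale_name}\t{pred.n}\t{pred.level_u:.3f}\n"
            )


def read_segments_tsv(path) -> dict[str, list[Segment]]:
    """Read back the TSV written by :func:`write_segments_tsv`."""
    df = pd.read_csv(path, sep="\t", comment="#")
    out: dict[str, list[Segment]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["protein_id"]), []).append(
            Segment(
                start=int(row["start"]),
                end=int(row["end"]),
                kind=str(row["kind"]),
                source=str(row.get("source", "detected")),
            )
        )
    return out


def write_segments_bed(
    predictions: Sequence[Prediction], handle: TextIO, params: dict | None = None
) -> None:
    """BED output: 0-based half-open, chrom = protein id, name = kind."""
    for line in _param_header(params):
        handle.write(line + "\n")
    for pred in predictions:
        for seg in pred.segments:
            handle.write(
                f"{pred.protein_id}\t{seg.start - 1}\t{seg.end}\t{seg.kind}\n"
            )


def read_segments_bed(path) -> dict[str, list[Segment]]:
    """Read BED back into 1-based inclusive segments (round-trip of the writer)."""
    out: dict[str, list[Segment]] = {}
    with open(path) as handle:
        for ln in handle:
            if not ln.strip() or ln.startswith("#"):
                continue
            chrom, start0, end0, name = ln.rstrip("\n").split("\t")[:4]
            out.setdefault(chrom, []).append(
                Segment(start=int(start0) + 1, end=int(end0), kind=name)
            )
    return out


def write_segments_gff3(
    predictions: Sequence[Prediction], handle: TextIO, params: dict | None = None
) -> None:
    """GFF3 with feature types Transmembrane_helix / Signal_peptide."""
    handle.write("##gff-version 3\n")
    for line in _param_header(params):
        handle.write(line + "\n")
    for pred in predictions:
        for i, seg in enumerate(pred.segments, start=1):
            handle.write(
                f"{pred.protein_id}\ttmcascade\t{_GFF3_TYPES[seg.kind]}\t"
                f"{seg.start}\t{seg.end}\t.\t.\t.\t"
                f"ID={pred.protein_id}.seg{i};source={seg.source};"
                f"scale={pred.scale_name};n={pred.n};u={pred.level_u:.3f}\n"
            )


def profile_table(seq: ProteinSequence, profile: HydroProfile) -> pd.DataFrame:
    """Per-residue table: position, residue, f_0 .. f_n, u."""
    data = {"position": range(1, seq.length + 1), "residue": list(seq.residues)}
    for n, series in enumerate(profile.stack):
        data[f"f_{n}"] = series
    data["u"] = profile.level_u
    return pd.DataFrame(data)


def write_profile_tsv(
    seq: ProteinSequence,
    profile: HydroProfile,
    handle: TextIO,
    params: dict | None = None,
) -> None:
    for line in _param_header(params):
        handle.write(line + "\n")
    profile_table(seq, profile).to_csv(handle, sep="\t", index=False, float_format="%.6g")
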