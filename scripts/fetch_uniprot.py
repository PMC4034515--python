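#!/usr/bin/env python
"""Download the benchmark UniProt sequences into data/uniprot/ (network required).

Usage:  python scripts/fetch_uniprot.py [ACCESSION ...]

With no arguments, fetches every accession used by the bundled GPCR
benchmark and the sequence-level worked examples.  The core library never
touches the network; this helper only stages FASTA files for
scripts/reproduce_benchmark.py --with-sequences and the sequence-level
acceptance tests.
"""

from __future__ import annotations

import sys
import urllib.request
from pathlib import Path

REPO_ROOT = Path(__file__).resolve().parent.parent
OUT_DIR = REPO_ROOT / "data" / "uniprot"
URL = "https://rest.uniprot.org/uniprotkb/{acc}.fasta"

BENCHMARK_ACCESSIONS = [
    "P47871", "P34998", "P07700", "P28222", "P41595",
    "P21453", "P08172", "P08483", "P25024", "P51681",
    "P35367", "P41145", "P42866", "P32300", "P41146",
    "P20789", "P25116", "Q8TCB6", "Q99835", "Q9UJ42",
    "Q9Y5N1", "Q9H3N8", "Q8NFJ5", "Q9GZP7", "P35414",
]


def fetch(accession: str) -> Path:
    OUT_DIR.mkdir(parents=True, exist_ok=True)
    dest = OUT_DIR / f"{accession}.fasta"
    with urllib.request.urlopen(URL.format(acc=accession), timeout=30) as resp:
        data = resp.read()
    if not data.startswith(b">"):
        raise RuntimeError(f"{accession}: response is not FASTA")
    dest.write_bytes(data)
    return dest


def main(argv: list[str]) -> int:
    accessions = argv or BENCHMARK_ACCESSIONS
    for acc in accessions:
        try:
            dest = fetch(acc)
            print(f"fetched {acc} -> {dest}")
        except Exception as exc:  # noqa: BLE001 - report and continue
            print(f"FAILED {acc}: {exc}", file=sys.stderr)
    return 0


if __name__ == "__main__":
    raise SystemExit(main(sys.argv[1:]))
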