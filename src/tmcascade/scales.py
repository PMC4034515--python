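"""Hydrophobicity scales and sequence encoding.

Seven per-residue hydrophobicity scales (H1..H7) drawn from the classical
hydropathy literature, spanning free-energy based scales (H1, H5, H6, H7),
crude class indicators (H2: hydrophobic vs rest; H3: hydrophobic /
neutral / hydrophilic), and a solvent-accessible-surface-area based scale
(H4).  A protein sequence is turned into the raw hydrophobicity series
f_0(k) = H_N[i(k)] by position-wise table lookup.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: One-letter codes of the 20 standard amino acids, in the conventional
#: alphabetical order used to index the scale table (i = 1..20).
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Codes accepted under the ``neutral-zero`` policy but mapped to 0.
NONSTANDARD_CODES: frozenset[str] = frozenset("XBZUO")

# Per-residue values for the seven scales, row order = AMINO_ACIDS.
#          H1     H2   H3    H4     H5     H6      H7
_TABLE = {
    "A": (1.8,   0,   0,    0.74,  0.62,  1.60,  -0.17),
    "C": (2.5,   1,   1,    0.91,  0.29,  2.00,   0.24),
    "D": (-3.5,  0,  -1,    0.62, -0.90, -9.20,  -1.23),
    "E": (-3.5,  0,  -1,    0.62, -0.74, -8.20,  -2.02),
    "F": (2.8,   1,   1,    0.88,  1.19,  3.70,   1.13),
    "G": (-0.4,  0,  -1,    0.72,  0.48,  1.00,  -0.01),
    "H": (-3.2,  0,   0,    0.78, -0.40, -3.00,  -0.96),
    "I": (4.5,   1,   1,    0.88,  1.38,  3.10,   0.31),
    "K": (-3.9,  0,  -1,    0.52, -1.50, -8.80,  -0.99),
    "L": (3.8,   1,   1,    0.85,  1.06,  2.80,   0.56),
    "M": (1.9,   1,   1,    0.85,  0.64,  3.40,   0.23),
    "N": (-3.5,  0,  -1,    0.63, -0.78, -4.80,  -1.23),
    "P": (-1.6,  0,  -1,    0.64,  0.12, -0.20,  -0.45),
    "Q": (-3.5,  0,  -1,    0.62, -0.85, -4.10,  -0.58),
    "R": (-4.5,  0,  -1,    0.64, -2.53, -12.3,  -0.81),
    "S": (-0.8,  0,  -1,    0.66, -0.18,  0.60,  -0.13),
    "T": (-0.7,  0,  -1,    0.70, -0.05,  1.20,  -0.14),
    "V": (4.2,   1,   1,    0.86,  1.08,  2.60,  -0.07),
    "W": (-0.9,  1,   1,    0.85,  0.81,  1.90,   1.85),
    "Y": (-1.3,  0,   0,    0.76,  0.26, -0.70,   0.94),
}

_CITATIONS = {
    "H1": "Kyte-Doolittle hydropathy (free-energy based)",
    "H2": "binary class indicator: hydrophobic {C,F,I,L,M,V,W} = 1, rest = 0",
    "H3": "ternary class indicator: hydrophobic = +1, neutral {A,H,Y} = 0, hydrophilic = -1",
    "H4": "buried-fraction scale 1 - <A>/A0 from solvent-accessible surface areas",
    "H5": "Eisenberg consensus hydrophobicity",
    "H6": "free-energy of transfer, water to hydrophobic medium",
    "H7": "statistical transfer free-energy scale",
}

SCALE_NAMES: tuple[str, ...] = ("H1", "H2", "H3", "H4", "H5", "H6", "H7")


@dataclass(frozen=True)
class HydrophobicityScale:
    """A named mapping from the 20 standard amino acids to numeric values."""

    name: str
    values: Mapping[str, float]
    citation: str = ""

    def __post_init__(self) -> None:
        if set(self.values) != set(AMINO_ACIDS):
            raise ValueError(
                f"scale {self.name!r} must map exactly the 20 standard amino acids"
            )
        object.__setattr__(self, "values", MappingProxyType(dict(self.values)))

    def __getitem__(self, code: str) -> float:
        return self.values[code]


_SCALES: dict[str, HydrophobicityScale] = {
    name: HydrophobicityScale(
        name=name,
        values={aa: float(_TABLE[aa][j]) for aa in AMINO_ACIDS},
        citation=_CITATIONS[name],
    )
    for j, name in enumerate(SCALE_NAMES)
}


def get_scale(name: str) -> HydrophobicityScale:
    """Return one of the seven built-in hydrophobicity scales.

    Parameters
    ----------
    name
        Scale identifier, one of ``H1`` .. ``H7`` (case-insensitive).

    Raises
    ------
    KeyError
        If *name* is not a defined scale identifier.
    """
    key = str(name).upper()
    if key not in _SCALES:
        raise KeyError(
            f"unknown hydrophobicity scale {name!r}; valid scales: {', '.join(SCALE_NAMES)}"
        )
    return _SCALES[key]


@dataclass(frozen=True)
class ProteinSequence:
    """A protein chain as a string of one-letter residue codes.

    Residues are upper-cased on construction; positions are 1-based
    (``k = 1..L``) throughout the package, matching the convention of
    residue-numbered annotation tables.
    """

    id: str
    residues: str
    description: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)


def encode_sequence(
    seq: ProteinSequence | str,
    scale: HydrophobicityScale | str,
    unknown_policy: str = "neutral-zero",
) -> np.ndarray:
    """Encode a sequence as the raw hydrophobicity series f_0(k).

    Element ``k`` (0-based in the returned array) is the scale value of the
    residue at position ``k + 1``.

    Parameters
    ----------
    seq
        Sequence object or plain residue string.
    scale
        Scale object or identifier (``H1`` .. ``H7``).
    unknown_policy
        ``"neutral-zero"`` maps non-standard codes (X, B, Z, U, O) to 0.0
        with a logged warning; ``"error"`` raises on any non-standard code,
        naming position and code.
    """
    if isinstance(seq, str):
        seq = ProteinSequence(id="<anonymous>", residues=seq)
    if isinstance(scale, str):
        scale = get_scale(scale)
    if unknown_policy not in ("neutral-zero", "error"):
        raise ValueError(
            f"unknown_policy must be 'neutral-zero' or 'error', got {unknown_policy!r}"
        )

    out = np.empty(len(seq), dtype=float)
    for idx, code in enumerate(seq.residues):
        try:
            out[idx] = scale.values[code]
        except KeyError:
            if unknown_policy == "error":
                raise ValueError(
                    f"non-standard residue code {code!r} at position {idx + 1} "
                    f"in sequence {seq.id!r}"
                ) from None
            out[idx] = 0.0
            logger.warning(
                "sequence %s: non-standard residue %r at position %d mapped to 0",
                seq.id,
                code,
                idx + 1,
            )
    return out


def scales_table() -> pd.DataFrame:
    """All seven scales as a DataFrame (columns: code, H1..H7)."""
    rows = [
        {"code": aa, **{name: _SCALES[name][aa] for name in SCALE_NAMES}}
        for aa in AMINO_ACIDS
    ]
    return pd.DataFrame(rows)


def export_scales_tsv(path) -> None:
    """Write the scale table as a tab-separated file."""
    scales_table().to_csv(path, sep="\t", index=False)
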