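"""Side-chain atomic composition of the 20 standard amino acids.

Each residue in a polypeptide contributes an invariant C2H3NO backbone
unit; everything beyond that is the side chain.  The counts below are the
heavy atoms (C, N, O, S; hydrogen is ignored) in each side chain, i.e. the
residue molecular formula minus one C2H3NO unit.  They are the weights
``w`` used by the elemental-content statistic: the mean number of
side-chain atoms of an element per residue of a protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Tuple

ELEMENTS: Tuple[str, ...] = ("C", "N", "O", "S")

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: side-chain heavy-atom counts, (C, N, O, S) per one-letter code
SIDECHAIN_ATOMS: Dict[str, Tuple[int, int, int, int]] = {
    "A": (1, 0, 0, 0),
    "R": (4, 3, 0, 0),
    "N": (2, 1, 1, 0),
    "D": (2, 0, 2, 0),
    "C": (1, 0, 0, 1),
    "E": (3, 0, 2, 0),
    "Q": (3, 1, 1, 0),
    "G": (0, 0, 0, 0),
    "H": (4, 2, 0, 0),
    "I": (4, 0, 0, 0),
    "L": (4, 0, 0, 0),
    "K": (4, 1, 0, 0),
    "M": (3, 0, 0, 1),
    "F": (7, 0, 0, 0),
    "P": (3, 0, 0, 0),
    "S": (1, 0, 1, 0),
    "T": (2, 0, 1, 0),
    "W": (9, 1, 0, 0),
    "Y": (7, 0, 1, 0),
    "V": (3, 0, 0, 0),
}

_ELEMENT_INDEX = {e: i for i, e in enumerate(ELEMENTS)}


@dataclass(frozen=True)
class AminoAcidAtomTable:
    """Lookup table of per-amino-acid side-chain heavy-atom counts.

    The default table covers the 20 standard amino acids.  A custom
    mapping (e.g. including selenocysteine) may be supplied, but every
    value must be a 4-tuple of non-negative integers ordered (C, N, O, S).
    """

    counts: Mapping[str, Tuple[int, int, int, int]] = field(
        default_factory=lambda: dict(SIDECHAIN_ATOMS)
    )

    def __post_init__(self) -> None:
        for aa, row in self.counts.items():
            if len(row) != len(ELEMENTS) or any(
                (not isinstance(c, int)) or c < 0 for c in row
            ):
                raise ValueError(
                    f"atom counts for {aa!r} must be 4 non-negative ints (C,N,O,S)"
                )

    def count(self, amino_acid: str, element: str) -> int:
        if element not in _ELEMENT_INDEX:
            raise KeyError(f"unknown element {element!r}; expected one of {ELEMENTS}")
        try:
            return self.counts[amino_acid][_ELEMENT_INDEX[element]]
        except KeyError:
            raise KeyError(f"unknown amino acid code {amino_acid!r}") from None

    def weights(self, element: str) -> Dict[str, int]:
        """Per-amino-acid counts of ``element`` as a plain dict."""
        if element not in _ELEMENT_INDEX:
            raise KeyError(f"unknown element {element!r}; expected one of {ELEMENTS}")
        j = _ELEMENT_INDEX[element]
        return {aa: row[j] for aa, row in self.counts.items()}


DEFAULT_ATOM_TABLE = AminoAcidAtomTable()


def sidechain_atom_count(amino_acid: str, element: str) -> int:
    """Number of side-chain atoms of ``element`` in one residue of ``amino_acid``.

    >>> sidechain_atom_count("G", "N")
    0
    >>> sidechain_atom_count("R", "N")
    3
    """
    return DEFAULT_ATOM_TABLE.count(amino_acid, element)
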