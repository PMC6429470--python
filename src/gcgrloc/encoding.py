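"""Reduced amino-acid alphabets.

Two many-to-one encodings of the 20 standard residues:

* a six-letter alphabet {H, L, S, P, G, C} used by the hexagonal
  chaos-game walk -- proline, glycine and cysteine keep their own
  groups for their unusual backbone chemistry, and the remaining 17
  residues split by hydropathy into strongly hydrophilic (H), strongly
  hydrophobic (L) and weakly hydrophilic/hydrophobic (S);
* a three-letter alphabet {F, D, S} used by the interval statistics --
  internal (F), external (D) and ambivalent (S) hydropathy groups.

The three-letter group names deliberately reuse amino-acid letters, so
encoded sequences are wrapped in distinct types and never re-encoded.
"""

from __future__ import annotations

from dataclasses import dataclass

SIX_LETTER_GROUPS: dict[str, str] = {
    "H": "HRDENQK",
    "L": "LIVAMF",
    "S": "STYW",
    "P": "P",
    "G": "G",
    "C": "C",
}

THREE_LETTER_GROUPS: dict[str, str] = {
    "F": "FILMV",
    "D": "DEHKNQR",
    "S": "STYCWGPA",
}


def _invert(groups: dict[str, str]) -> dict[str, str]:
    table: dict[str, str] = {}
    for letter, members in groups.items():
        for aa in members:
            if aa in table:
                raise AssertionError(f"amino acid {aa} assigned to two groups")
            table[aa] = letter
    if set(table) != set("ACDEFGHIKLMNPQRSTVWY"):
        raise AssertionError("groups do not partition the 20 standard amino acids")
    return table

# Built (and partition-checked) at import time.
_SIX_TABLE = _invert(SIX_LETTER_GROUPS)
_THREE_TABLE = _invert(THREE_LETTER_GROUPS)


@dataclass(frozen=True)
class SixLetterSequence:
    """A sequence over {H, L, S, P, G, C}, same length as its source."""

    symbols: str
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass(frozen=True)
class ThreeLetterSequence:
    """A sequence over {F, D, S}, same length as its source."""

    symbols: str
    source_id: str = ""

    def __len__(self) -> int:
        return len(self.symbols)


def _encode(sequence: str, table: dict[str, str], alphabet_name: str) -> str:
    if not sequence:
        raise ValueError("cannot encode an empty sequence")
    try:
        return "".join(table[aa] for aa in sequence.upper())
    except KeyError as exc:
        raise ValueError(
            f"character {exc.args[0]!r} has no {alphabet_name} group"
        ) from None


def encode_six(sequence: str, source_id: str = "") -> SixLetterSequence:
    """Map an amino-acid sequence onto the six-letter hexagon alphabet.

    >>> encode_six("YAMQESHFTCI").symbols
    'SLLHHSHLSCL'
    """
    return SixLetterSequence(symbols=_encode(sequence, _SIX_TABLE, "six-letter"), source_id=source_id)


def encode_three(sequence: str, source_id: str = "") -> ThreeLetterSequence:
    """Map an amino-acid sequence onto the three-letter hydropathy alphabet.

    >>> encode_three("YAMQESHFTCI").symbols
    'SSFDDSDFSSF'
    """
    return ThreeLetterSequence(symbols=_encode(sequence, _THREE_TABLE, "three-letter"), source_id=source_id)
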