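"""Strand transforms and translation of extracted inserts.

The randomized region may be sequenced on either strand and in either
orientation relative to the displayed peptide, so four read-out modes are
offered: forward (as read), forward complement (base-complemented, same
order), reverse (character-reversed), and reverse complement.  The chosen
transform is applied to each frame-valid insert and the result is
translated with the standard genetic code (NCBI table 1).

Counting downstream is keyed by the insert *as extracted* (pre-transform),
so synonymous DNA sequences remain distinct rows and the counts do not
depend on the chosen mode.
"""

from __future__ import annotations

from enum import Enum
from typing import Iterable

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import complement

_CODON_TO_AA = dict(standard_dna_table.forward_table)
_CODON_TO_AA.update({codon: "*" for codon in standard_dna_table.stop_codons})


class TranslationMode(str, Enum):
    """How an extracted insert is read out before translation."""

    FORWARD = "forward"
    FORWARD_COMPLEMENT = "forward_complement"
    REVERSE = "reverse"
    REVERSE_COMPLEMENT = "reverse_complement"


class FrameError(ValueError):
    """Raised when a sequence whose length is not divisible by 3 reaches a
    stage that requires an intact reading frame; such sequences must be
    filtered upstream by extraction's frame check."""


def transform(insert: str, mode: TranslationMode | str) -> str:
    """Apply the strand/orientation transform for *mode*.

    Length is preserved.  Raises :class:`FrameError` for inserts whose
    length is not divisible by 3 (they should never reach this stage).
    """
    if len(insert) % 3 != 0:
        raise FrameError(
            f"insert length {len(insert)} is not divisible by 3; "
            "frame failures must be filtered before transformation"
        )
    mode = TranslationMode(mode)
    if mode is TranslationMode.FORWARD:
        return insert
    if mode is TranslationMode.FORWARD_COMPLEMENT:
        return complement(insert)
    if mode is TranslationMode.REVERSE:
        return insert[::-1]
    return complement(insert)[::-1]


def translate(dna: str) -> str:
    """Translate codon-by-codon with the standard genetic code.

    Stop codons emit ``*`` and are retained; any codon containing a symbol
    outside A/C/G/T (e.g. an ``N`` call) emits ``X`` instead of discarding
    the read.  Input length must be divisible by 3.
    """
    if len(dna) % 3 != 0:
        raise FrameError(
            f"cannot translate length {len(dna)}: not divisible by 3"
        )
    peptide = []
    for i in range(0, len(dna), 3):
        codon = dna[i : i + 3]
        peptide.append(_CODON_TO_AA.get(codon, "X"))
    return "".join(peptide)


def translate_round(
    inserts: Iterable[str], mode: TranslationMode | str
) -> list[tuple[str, str]]:
    """Translate a round's inserts; returns ``(dna, peptide)`` pairs.

    Order-preserving.  The ``dna`` element is the insert as extracted
    (before the mode transform) so it can serve as the counting key.
    """
    mode = TranslationMode(mode)
    return [(insert, translate(transform(insert, mode))) for insert in inserts]
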