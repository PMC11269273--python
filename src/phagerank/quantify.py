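"""Per-round tallying and parts-per-million normalization.

Counting is done at the DNA level: distinct synonymous nucleotide
sequences stay distinct rows even when they encode the same peptide.
Frequencies are normalized to parts per million of the round's total
frame-valid extracted inserts, so every round sums to exactly 1e6 ppm and
rounds of different sequencing depth are directly comparable.
"""

from __future__ import annotations

import datetime as _dt
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

PPM_SCALE = 1_000_000.0


@dataclass(frozen=True)
class CountRow:
    peptide: str
    raw_count: int
    ppm: float


@dataclass
class CountTable:
    """Counts and ppm frequencies for one selection round.

    ``rows`` maps each distinct extracted DNA sequence to its peptide,
    raw count and ppm frequency.  ``total_counted`` is the ppm denominator:
    the number of frame-valid extracted inserts in the round.
    """

    selection_name: str
    rows: dict[str, CountRow]
    total_counted: int
    frame_fail_count: int = 0
    user: str = ""
    processed_date: str = field(
        default_factory=lambda: _dt.date.today().isoformat()
    )

    def ppm(self, dna: str) -> float:
        """ppm of *dna* in this round; 0.0 if absent."""
        row = self.rows.get(dna)
        return row.ppm if row is not None else 0.0

    def to_frame(self) -> pd.DataFrame:
        """Rows as a DataFrame sorted by descending raw count."""
        frame = pd.DataFrame(
            [
                (dna, row.peptide, row.raw_count, row.ppm)
                for dna, row in self.rows.items()
            ],
            columns=["dna", "peptide", "raw_count", "ppm"],
        )
        return frame.sort_values(
            ["raw_count", "dna"], ascending=[False, True], ignore_index=True
        )


def tally(pairs: Iterable[tuple[str, str]]) -> dict[str, tuple[str, int]]:
    """Count exact DNA multiplicities; returns ``dna -> (peptide, count)``."""
    counts: Counter[str] = Counter()
    peptides: dict[str, str] = {}
    for dna, peptide in pairs:
        counts[dna] += 1
        peptides.setdefault(dna, peptide)
    return {dna: (peptides[dna], n) for dna, n in counts.items()}


def normalize_ppm(
    counts: Mapping[str, tuple[str, int]], total: int
) -> dict[str, CountRow]:
    """Attach ppm = count / total * 1e6 to every row.

    *total* must equal the sum of counts (it is the round's frame-valid
    insert total); a zero total means the round had no extractable reads
    and is an error.
    """
    if total == 0:
        raise ValueError("no extractable reads in round (total == 0)")
    observed = sum(n for _, n in counts.values())
    if observed != total:
        raise ValueError(
            f"total {total} does not match summed counts {observed}"
        )
    return {
        dna: CountRow(peptide, n, n / total * PPM_SCALE)
        for dna, (peptide, n) in counts.items()
    }


def build_count_table(
    pairs: Iterable[tuple[str, str]],
    selection_name: str,
    frame_fail_count: int = 0,
    user: str = "",
    processed_date: str | None = None,
) -> CountTable:
    """Tally and normalize one round's ``(dna, peptide)`` pairs."""
    counts = tally(pairs)
    total = sum(n for _, n in counts.values())
    rows = normalize_ppm(counts, total)
    kwargs = {} if processed_date is None else {"processed_date": processed_date}
    return CountTable(
        selection_name=selection_name,
        rows=rows,
        total_counted=total,
        frame_fail_count=frame_fail_count,
        user=user,
        **kwargs,
    )
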