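"""Locate the randomized insert between two constant framing anchors.

Phage-display amplicons carry a user-defined randomized region flanked by
constant vector sequence.  Each read is scanned for the *first* occurrence
of the left anchor; the insert ends at the nearest following occurrence of
the right anchor (shortest-match semantics, at most one insert per read).
Anchor matching is exact; reads whose anchors carry point mutations are
counted as misses and can be rescued with :func:`enumerate_anchor_variants`.

Matched inserts whose length is not divisible by 3 indicate a
frame-breaking indel and are routed to a separate frame-failure list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .fastq_io import FastqRecord

_DNA_ALPHABET = frozenset("ACGT")
_BASES = "ACGT"


class PatternError(ValueError):
    """Raised for an invalid anchor pair."""


@dataclass(frozen=True)
class SearchPattern:
    """The two framing nucleotide anchors defining the region of interest.

    Equivalent to a non-greedy regex ``LEFT(.+?)RIGHT`` applied once per
    read, except that an empty insert (anchors directly adjacent) is also
    matched.
    """

    left_anchor: str
    right_anchor: str
    label: str = ""

    def __post_init__(self) -> None:
        for name, anchor in (
            ("left_anchor", self.left_anchor),
            ("right_anchor", self.right_anchor),
        ):
            if not anchor:
                raise PatternError(f"{name} must be non-empty")
            bad = set(anchor.upper()) - _DNA_ALPHABET
            if bad:
                raise PatternError(
                    f"{name} contains non-ACGT character(s): "
                    f"{', '.join(sorted(bad))!s}"
                )
        object.__setattr__(self, "left_anchor", self.left_anchor.upper())
        object.__setattr__(self, "right_anchor", self.right_anchor.upper())


def compile_pattern(
    left_anchor: str, right_anchor: str, label: str = ""
) -> SearchPattern:
    """Validate and uppercase an anchor pair into a :class:`SearchPattern`."""
    return SearchPattern(left_anchor, right_anchor, label)


@dataclass
class ExtractionResult:
    """Per-round extraction outcome.

    ``inserts`` holds frame-valid inserts (length divisible by 3),
    ``frame_failures`` holds matched inserts that break the reading frame,
    and ``miss_count`` counts reads with no anchor match.  The three
    partition the input: ``len(inserts) + len(frame_failures) + miss_count
    == total_reads``.
    """

    inserts: list[str] = field(default_factory=list)
    frame_failures: list[str] = field(default_factory=list)
    miss_count: int = 0
    total_reads: int = 0
    missed_reads: list[FastqRecord] = field(default_factory=list)

    @property
    def frame_failure_frequency(self) -> float:
        """Fraction of matched reads whose insert breaks the frame."""
        matched = len(self.inserts) + len(self.frame_failures)
        return len(self.frame_failures) / matched if matched else 0.0


def extract_insert(sequence: str, pattern: SearchPattern) -> Optional[str]:
    """Return the insert framed by the anchors, or ``None`` for no match.

    Only the first occurrence of the left anchor is considered; the right
    anchor is searched starting immediately after it, so the shortest
    (non-greedy) insert is returned and overlapping anchors cannot match.
    An empty insert (adjacent anchors) is returned as ``""``.
    """
    left = sequence.find(pattern.left_anchor)
    if left == -1:
        return None
    start = left + len(pattern.left_anchor)
    right = sequence.find(pattern.right_anchor, start)
    if right == -1:
        return None
    return sequence[start:right]


def extract_round(
    records: Iterable[FastqRecord],
    pattern: SearchPattern,
    keep_missed_reads: bool = False,
) -> ExtractionResult:
    """Extract inserts from a whole round with one fixed pattern.

    Matched inserts are routed by the frame check (length % 3); unmatched
    reads increment ``miss_count``.  With ``keep_missed_reads`` the missed
    records themselves are retained, e.g. for anchor-variant re-search.
    """
    result = ExtractionResult()
    for record in records:
        result.total_reads += 1
        insert = extract_insert(record.sequence, pattern)
        if insert is None:
            result.miss_count += 1
            if keep_missed_reads:
                result.missed_reads.append(record)
        elif len(insert) % 3 == 0:
            result.inserts.append(insert)
        else:
            result.frame_failures.append(insert)
    return result


def enumerate_anchor_variants(pattern: SearchPattern) -> list[SearchPattern]:
    """All patterns with exactly one base substituted in one anchor.

    Used to rescue reads whose constant region carries a point mutation:
    re-searching misses with every single-substitution anchor variant
    recovers them.  Returns ``3 * (len(left) + len(right))`` patterns; the
    original is not included.
    """
    variants: list[SearchPattern] = []
    for side in ("left", "right"):
        anchor = pattern.left_anchor if side == "left" else pattern.right_anchor
        for i, original_base in enumerate(anchor):
            for base in _BASES:
                if base == original_base:
                    continue
                mutated = anchor[:i] + base + anchor[i + 1 :]
                if side == "left":
                    variants.append(
                        SearchPattern(mutated, pattern.right_anchor)
                    )
                else:
                    variants.append(
                        SearchPattern(pattern.left_anchor, mutated)
                    )
    return variants


def rescue_with_variants(
    missed: Iterable[FastqRecord], pattern: SearchPattern
) -> dict[str, tuple[SearchPattern, str]]:
    """Re-search missed reads with all single-SNV anchor variants.

    Returns a map ``read_id -> (variant pattern, insert)`` for every missed
    read recovered by some variant.  Variants are tried in enumeration
    order and the first matching variant wins, which makes the result
    deterministic.
    """
    variants = enumerate_anchor_variants(pattern)
    recovered: dict[str, tuple[SearchPattern, str]] = {}
    for record in missed:
        for variant in variants:
            insert = extract_insert(record.sequence, variant)
            if insert is not None:
                recovered[record.read_id] = (variant, insert)
                break
    return recovered
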