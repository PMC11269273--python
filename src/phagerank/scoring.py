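"""Control-aware enrichment and empty scores, ranking and filtering.

Candidate binders are ranked by comparing the final target round against
the control selections of a campaign:

* **enrichment score** = ppm in the last target round / ppm in the naive
  library — how strongly selection amplified the sequence over its
  starting abundance;
* **empty score** = ppm in the last target round / ppm in the matched
  round of the target-free (empty) selection — how target-dependent that
  amplification was.  The empty score is the primary ranking key: plastic
  binders and amplification-advantaged clones enrich in the empty
  selection too and score near 1.

Both ratios use ppm frequencies so sequencing depth cancels.  A sequence
absent from a control round would give a zero denominator; a configurable
ppm floor (default 0.5 ppm, half the smallest frequency observable at the
1e6 scale) replaces zero denominators so "never seen in control" ranks
strongest instead of being dropped.

A direct control (target selection continued one round without target) is
reported as a ratio column and may optionally be used as a filter; no
hard rule is applied by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .quantify import CountTable

DEFAULT_FLOOR_PPM = 0.5

EVALUATION_COLUMNS = [
    "rank",
    "dna",
    "peptide",
    "empty_score",
    "enrichment_score",
    "target3_ppm",
    "target2_ppm",
    "target1_ppm",
    "library_ppm",
    "empty3_ppm",
    "direct_control_ppm",
    "direct_control_ratio",
]


class ScoringConfigError(ValueError):
    """Raised when the rounds required for a requested score are missing."""


@dataclass
class RoundSet:
    """The labeled rounds of one selection campaign.

    ``targets`` holds the target-selection rounds in order (up to three);
    the last entry is the round the scores are computed from.  ``empties``
    are the rounds of a selection run entirely without target;
    ``direct_control`` is the target selection continued one round without
    target; ``library`` is the naive library sequenced before selection.
    """

    targets: list[CountTable]
    empties: list[CountTable] = field(default_factory=list)
    direct_control: Optional[CountTable] = None
    library: Optional[CountTable] = None

    def __post_init__(self) -> None:
        if not self.targets:
            raise ScoringConfigError("at least one target round is required")
        if len(self.targets) > 3:
            raise ScoringConfigError("at most three target rounds supported")

    @property
    def final_target(self) -> CountTable:
        return self.targets[-1]

    @property
    def final_empty(self) -> Optional[CountTable]:
        return self.empties[-1] if self.empties else None


@dataclass(frozen=True)
class ScoredRecord:
    dna: str
    peptide: str
    target3_ppm: float
    library_ppm: float
    empty3_ppm: float
    enrichment_score: float
    empty_score: float
    direct_control_ppm: Optional[float] = None
    direct_control_ratio: Optional[float] = None
    target1_ppm: Optional[float] = None
    target2_ppm: Optional[float] = None


@dataclass
class ScoringConfig:
    """Scoring and filtering knobs.

    floor_ppm
        Denominator floor replacing zero control frequencies.
    min_target_ppm, min_enrichment_score, max_direct_control_ratio
        Optional filters applied after scoring; ``None`` disables each.
    """

    floor_ppm: float = DEFAULT_FLOOR_PPM
    min_target_ppm: Optional[float] = None
    min_enrichment_score: Optional[float] = None
    max_direct_control_ratio: Optional[float] = None

    def __post_init__(self) -> None:
        if self.floor_ppm <= 0:
            raise ScoringConfigError("floor_ppm must be > 0")


def enrichment_score(
    target3_ppm: float, library_ppm: float, floor: float = DEFAULT_FLOOR_PPM
) -> float:
    """ppm in the final target round over ppm in the naive library.

    A zero library frequency is replaced by *floor*.
    """
    if floor <= 0:
        raise ScoringConfigError("floor must be > 0")
    return target3_ppm / max(library_ppm, floor)


def empty_score(
    target3_ppm: float, empty3_ppm: float, floor: float = DEFAULT_FLOOR_PPM
) -> float:
    """ppm in the final target round over ppm in the matched empty round."""
    if floor <= 0:
        raise ScoringConfigError("floor must be > 0")
    return target3_ppm / max(empty3_ppm, floor)


def evaluate(
    rounds: RoundSet, config: ScoringConfig | None = None
) -> list[ScoredRecord]:
    """Score and rank every sequence of the final target round.

    Records are sorted by empty score descending, ties broken by
    enrichment score, then final-target ppm (both descending), then
    lexicographic DNA — a total order, so the output is deterministic.
    Optional filters from *config* are applied after scoring.
    """
    config = config or ScoringConfig()
    if rounds.library is None:
        raise ScoringConfigError(
            "enrichment score requires the naive library round"
        )
    final_empty = rounds.final_empty
    if final_empty is None:
        raise ScoringConfigError(
            "empty score requires the final empty-selection round"
        )

    target = rounds.final_target
    earlier = rounds.targets[:-1]
    records: list[ScoredRecord] = []
    for dna, row in target.rows.items():
        t3 = row.ppm
        lib = rounds.library.ppm(dna)
        e3 = final_empty.ppm(dna)
        direct_ppm = direct_ratio = None
        if rounds.direct_control is not None:
            direct_ppm = rounds.direct_control.ppm(dna)
            direct_ratio = direct_ppm / max(t3, config.floor_ppm)
        records.append(
            ScoredRecord(
                dna=dna,
                peptide=row.peptide,
                target3_ppm=t3,
                library_ppm=lib,
                empty3_ppm=e3,
                enrichment_score=enrichment_score(t3, lib, config.floor_ppm),
                empty_score=empty_score(t3, e3, config.floor_ppm),
                direct_control_ppm=direct_ppm,
                direct_control_ratio=direct_ratio,
                target1_ppm=earlier[0].ppm(dna) if len(earlier) >= 1 else None,
                target2_ppm=earlier[1].ppm(dna) if len(earlier) >= 2 else None,
            )
        )

    records.sort(
        key=lambda r: (
            -r.empty_score,
            -r.enrichment_score,
            -r.target3_ppm,
            r.dna,
        )
    )

    def keep(r: ScoredRecord) -> bool:
        if config.min_target_ppm is not None and r.target3_ppm < config.min_target_ppm:
            return False
        if (
            config.min_enrichment_score is not None
            and r.enrichment_score < config.min_enrichment_score
        ):
            return False
        if (
            config.max_direct_control_ratio is not None
            and r.direct_control_ratio is not None
            and r.direct_control_ratio > config.max_direct_control_ratio
        ):
            return False
        return True

    return [r for r in records if keep(r)]


def evaluation_frame(records: list[ScoredRecord]) -> pd.DataFrame:
    """Evaluation table as a DataFrame with the fixed export column order."""
    frame = pd.DataFrame(
        [
            {
                "rank": i + 1,
                "dna": r.dna,
                "peptide": r.peptide,
                "empty_score": r.empty_score,
                "enrichment_score": r.enrichment_score,
                "target3_ppm": r.target3_ppm,
                "target2_ppm": r.target2_ppm,
                "target1_ppm": r.target1_ppm,
                "library_ppm": r.library_ppm,
                "empty3_ppm": r.empty3_ppm,
                "direct_control_ppm": r.direct_control_ppm,
                "direct_control_ratio": r.direct_control_ratio,
            }
            for i, r in enumerate(records)
        ],
        columns=EVALUATION_COLUMNS,
    )
    return frame
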