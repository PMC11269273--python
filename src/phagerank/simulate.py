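"""Synthetic phage-display selection campaigns with ground truth.

Generates the full set of FASTQ files one campaign provides — target
rounds 1..k, matched empty-selection rounds, a direct control, and the
naive library — plus a JSON-serializable manifest recording the true
multiplicity of every insert per round and the identity of every
corrupted read.  Every pipeline stage can therefore be checked exactly,
without external sequencing data.

The model:

* the library holds ``n_library_sequences`` distinct random inserts whose
  abundances follow a Zipf law (exponent 1.1 by default), the
  characteristic skew of real phage libraries;
* planted binders are library members whose weight is multiplied by their
  enrichment factor once per target round; empty rounds resample the
  background without that advantage; the direct control carries the
  advantage through round k-1 and then one neutral round;
* each round's reads are a multinomial draw of ``reads_per_round`` from
  the round's (deterministically evolved, renormalized) weight vector;
* each read is random pad + left anchor + insert + right anchor + random
  pad; a fraction ``anchor_mutation_rate`` of reads receives one random
  anchor point mutation (these become extraction misses) and a disjoint
  fraction ``frameshift_rate`` receives a 1-nt deletion inside the insert
  (these become frame failures).

Reads are rejection-sampled so that pads and inserts never create
spurious anchor occurrences and every planted corruption has exactly its
intended effect; with a fixed seed the output is byte-identical across
runs, and the manifest counts match extraction outcomes exactly rather
than statistically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .extraction import SearchPattern, extract_insert
from .fastq_io import FastqRecord, write_fastq

_BASES = np.array(list("ACGT"))

DEFAULT_LEFT_ANCHOR = "GATTCCAGG"
DEFAULT_RIGHT_ANCHOR = "TACGACCCG"


class SpecError(ValueError):
    """Raised for a contradictory campaign specification."""


@dataclass(frozen=True)
class CampaignSpec:
    """Parameters of one synthetic selection campaign.

    ``planted_binders`` maps insert DNA to its per-round enrichment
    factor; planted sequences become library members automatically.  The
    corruption rates must sum to less than 1 (each read receives at most
    one corruption).
    """

    n_library_sequences: int = 1000
    insert_length_nt: int = 27
    rounds: int = 3
    planted_binders: tuple[tuple[str, float], ...] = ()
    zipf_exponent: float = 1.1
    reads_per_round: int = 50_000
    left_anchor: str = DEFAULT_LEFT_ANCHOR
    right_anchor: str = DEFAULT_RIGHT_ANCHOR
    anchor_mutation_rate: float = 0.0
    frameshift_rate: float = 0.0
    pad_length_range: tuple[int, int] = (5, 15)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.insert_length_nt % 3 != 0 or self.insert_length_nt <= 0:
            raise SpecError("insert_length_nt must be positive and divisible by 3")
        if not 1 <= self.rounds <= 3:
            raise SpecError("rounds must be between 1 and 3")
        if not (0 <= self.anchor_mutation_rate < 1) or not (
            0 <= self.frameshift_rate < 1
        ):
            raise SpecError("corruption rates must lie in [0, 1)")
        if self.anchor_mutation_rate + self.frameshift_rate >= 1:
            raise SpecError("corruption rates must sum to less than 1")
        if self.n_library_sequences < max(1, len(self.planted_binders)):
            raise SpecError("library smaller than the planted binder set")
        for dna, factor in self.planted_binders:
            if len(dna) != self.insert_length_nt:
                raise SpecError(
                    f"planted binder {dna!r} has length {len(dna)}, "
                    f"expected {self.insert_length_nt}"
                )
            if set(dna) - set("ACGT"):
                raise SpecError(f"planted binder {dna!r} is not plain DNA")
            if factor <= 0:
                raise SpecError("enrichment factors must be positive")

    @property
    def pattern(self) -> SearchPattern:
        return SearchPattern(self.left_anchor, self.right_anchor)


@dataclass
class RoundTruth:
    """Ground truth for one generated round."""

    multiplicities: dict[str, int] = field(default_factory=dict)
    snv_read_ids: list[str] = field(default_factory=list)
    frameshift_read_ids: list[str] = field(default_factory=list)
    total_reads: int = 0


@dataclass
class Manifest:
    """Ground truth for a whole campaign.

    ``rounds`` maps a role name (``target_1`` .. ``target_k``,
    ``empty_1`` .. ``empty_k``, ``direct_control``, ``library``) to its
    :class:`RoundTruth`; ``fastq_paths`` maps the same roles to the
    written files.  Multiplicities cover clean reads only, so per round
    they sum to ``total_reads`` minus the corrupted-read count.
    """

    spec: CampaignSpec
    library_sequences: list[str]
    rounds: dict[str, RoundTruth] = field(default_factory=dict)
    fastq_paths: dict[str, str] = field(default_factory=dict)
    # in-memory copies of the generated reads, not serialized
    records_by_round: dict[str, list[FastqRecord]] = field(
        default_factory=dict, repr=False
    )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "spec": dataclasses.asdict(self.spec),
            "library_sequences": self.library_sequences,
            "fastq_paths": self.fastq_paths,
            "rounds": {
                name: {
                    "multiplicities": truth.multiplicities,
                    "snv_read_ids": truth.snv_read_ids,
                    "frameshift_read_ids": truth.frameshift_read_ids,
                    "total_reads": truth.total_reads,
                }
                for name, truth in self.rounds.items()
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _make_library(spec: CampaignSpec, rng: np.random.Generator) -> list[str]:
    """Distinct inserts, none containing either anchor, planted included.

    The returned order is random, and Zipf weights are assigned by list
    position, so planted binders land at random abundance ranks.
    """
    anchors = (spec.left_anchor, spec.right_anchor)
    sequences: set[str] = {dna for dna, _ in spec.planted_binders}
    while len(sequences) < spec.n_library_sequences:
        candidate = _random_dna(rng, spec.insert_length_nt)
        if any(a in candidate for a in anchors):
            continue
        sequences.add(candidate)
    ordered = sorted(sequences)
    rng.shuffle(ordered)
    return ordered


def _zipf_weights(n: int, exponent: float) -> np.ndarray:
    ranks = np.arange(1, n + 1, dtype=float)
    weights = ranks ** (-exponent)
    return weights / weights.sum()


def _round_weights(
    base: np.ndarray, factors: np.ndarray, advantage_rounds: int
) -> np.ndarray:
    weights = base * factors**advantage_rounds
    return weights / weights.sum()


def _build_clean_read(
    insert: str, spec: CampaignSpec, rng: np.random.Generator
) -> str:
    """Assemble pad+anchor+insert+anchor+pad; redraw pads until extraction
    of the read returns exactly the intended insert from the intended
    anchor positions."""
    lo, hi = spec.pad_length_range
    pattern = spec.pattern
    while True:
        left_pad = _random_dna(rng, int(rng.integers(lo, hi + 1)))
        right_pad = _random_dna(rng, int(rng.integers(lo, hi + 1)))
        read = left_pad + spec.left_anchor + insert + spec.right_anchor + right_pad
        if read.find(spec.left_anchor) != len(left_pad):
            continue
        if extract_insert(read, pattern) == insert:
            return read


def _apply_anchor_snv(
    read: str, insert: str, spec: CampaignSpec, rng: np.random.Generator
) -> str:
    """Mutate one random anchor base; redraw until the read no longer
    matches the exact pattern (so every planted SNV is a true miss)."""
    left_start = read.find(spec.left_anchor)
    right_start = left_start + len(spec.left_anchor) + len(insert)
    anchor_positions = list(
        range(left_start, left_start + len(spec.left_anchor))
    ) + list(range(right_start, right_start + len(spec.right_anchor)))
    pattern = spec.pattern
    while True:
        pos = int(rng.choice(anchor_positions))
        alternatives = [b for b in "ACGT" if b != read[pos]]
        base = alternatives[int(rng.integers(0, 3))]
        mutated = read[:pos] + base + read[pos + 1 :]
        if extract_insert(mutated, pattern) is None:
            return mutated


def _apply_frameshift(
    read: str, insert: str, spec: CampaignSpec, rng: np.random.Generator
) -> str:
    """Delete one base inside the insert; redraw until extraction yields
    an insert of length L-1 (a guaranteed frame failure)."""
    left_start = read.find(spec.left_anchor)
    insert_start = left_start + len(spec.left_anchor)
    pattern = spec.pattern
    while True:
        offset = int(rng.integers(0, len(insert)))
        pos = insert_start + offset
        mutated = read[:pos] + read[pos + 1 :]
        extracted = extract_insert(mutated, pattern)
        if extracted is not None and len(extracted) == len(insert) - 1:
            return mutated


def _generate_round(
    name: str,
    weights: np.ndarray,
    library: list[str],
    spec: CampaignSpec,
    rng: np.random.Generator,
) -> tuple[list[FastqRecord], RoundTruth]:
    counts = rng.multinomial(spec.reads_per_round, weights)
    truth = RoundTruth(total_reads=spec.reads_per_round)
    records: list[FastqRecord] = []
    read_index = 0
    for seq_index in np.nonzero(counts)[0]:
        insert = library[seq_index]
        for _ in range(int(counts[seq_index])):
            read_index += 1
            read_id = f"{name}_{read_index}"
            read = _build_clean_read(insert, spec, rng)
            u = rng.random()
            if u < spec.anchor_mutation_rate:
                read = _apply_anchor_snv(read, insert, spec, rng)
                truth.snv_read_ids.append(read_id)
            elif u < spec.anchor_mutation_rate + spec.frameshift_rate:
                read = _apply_frameshift(read, insert, spec, rng)
                truth.frameshift_read_ids.append(read_id)
            else:
                truth.multiplicities[insert] = (
                    truth.multiplicities.get(insert, 0) + 1
                )
            records.append(
                FastqRecord(
                    read_id=read_id, sequence=read, quality="I" * len(read)
                )
            )
    return records, truth


def generate_campaign(
    spec: CampaignSpec, out_dir: str | Path | None = None
) -> Manifest:
    """Generate all rounds of a campaign; optionally write FASTQ files.

    With *out_dir* set, one FASTQ per round plus ``manifest.json`` are
    written there and the manifest records the paths.  Fixed seed gives
    byte-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    library = _make_library(spec, rng)
    base = _zipf_weights(len(library), spec.zipf_exponent)
    factor_by_seq = dict(spec.planted_binders)
    factors = np.array([factor_by_seq.get(seq, 1.0) for seq in library])

    manifest = Manifest(spec=spec, library_sequences=library)
    plan: list[tuple[str, np.ndarray]] = [
        ("library", _round_weights(base, factors, 0))
    ]
    for r in range(1, spec.rounds + 1):
        plan.append((f"target_{r}", _round_weights(base, factors, r)))
    for r in range(1, spec.rounds + 1):
        plan.append((f"empty_{r}", _round_weights(base, factors, 0)))
    plan.append(
        ("direct_control", _round_weights(base, factors, spec.rounds - 1))
    )

    out_path = Path(out_dir) if out_dir is not None else None
    records_by_round: dict[str, list[FastqRecord]] = {}
    for name, weights in plan:
        records, truth = _generate_round(name, weights, library, spec, rng)
        manifest.rounds[name] = truth
        records_by_round[name] = records
        if out_path is not None:
            out_path.mkdir(parents=True, exist_ok=True)
            fastq = out_path / f"{name}.fastq"
            write_fastq(records, fastq)
            manifest.fastq_paths[name] = str(fastq)
    if out_path is not None:
        manifest.to_json(out_path / "manifest.json")
    manifest.records_by_round = records_by_round
    return manifest


def pick_planted_binders(
    spec_like_seed: int,
    n_binders: int,
    factor: float,
    insert_length_nt: int = 27,
    left_anchor: str = DEFAULT_LEFT_ANCHOR,
    right_anchor: str = DEFAULT_RIGHT_ANCHOR,
) -> tuple[tuple[str, float], ...]:
    """Draw random anchor-free binder sequences with a common factor."""
    rng = np.random.default_rng(spec_like_seed)
    binders: set[str] = set()
    while len(binders) < n_binders:
        candidate = _random_dna(rng, insert_length_nt)
        if left_anchor in candidate or right_anchor in candidate:
            continue
        binders.add(candidate)
    return tuple((dna, factor) for dna in sorted(binders))
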