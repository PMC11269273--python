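# Methods

## Insert extraction

Each amplicon read is scanned for the left framing anchor; the insert is
the substring between the *first* left-anchor occurrence and the nearest
following right-anchor occurrence (the semantics of the non-greedy
pattern `LEFT(.+?)RIGHT`, evaluated once per read, so a read can yield
at most one insert). Implementation details that pin down edge cases:

* Anchor matching is exact. A single base-call error inside an anchor
  makes the read a **miss**; misses are counted, and can be re-searched
  with the 3·(|left|+|right|) single-substitution anchor variants
  (`enumerate_anchor_variants` / the `variants` command), which reports
  rescued reads separately from the main analysis rather than merging
  them.
* If the left anchor occurs more than once, only its first occurrence
  is used — even when a later occurrence would pair with a right
  anchor. The right-anchor search starts at the position immediately
  after the left anchor ends, so overlapping anchors cannot match.
* An empty insert (anchors directly adjacent) has length 0, which is
  divisible by 3; it is kept and translates to the empty peptide.
* Reads are uppercased on ingest; `N` can never match an exact anchor,
  and an `N` inside the insert passes through to translation.

Inserts whose length is not divisible by 3 indicate a frame-breaking
indel; they are routed to a separate frame-failure list and the
per-round frame-failure frequency is reported. This is the pipeline's
only read-discard rule besides anchor misses.

The extraction path is verified against an independent brute-force
oracle (enumerate all occurrences of both anchors, take the first left
and the nearest following right) on randomized reads that mix matches,
misses, and multi-anchor layouts.

## Translation

Four read-out modes cover both strands and orientations: forward,
forward complement (base-complement in place), reverse
(character-reversal), reverse complement. After the transform, codons
are translated with the standard genetic code (NCBI table 1, via
Biopython's codon table). Stop codons are rendered `*` and retained;
codons containing a non-ACGT symbol render `X`. Both choices avoid
silent data loss: the frame check is deliberately the only filter, and
stop- or `X`-containing peptides remain visible for downstream
inspection. Counting is keyed by the insert *as extracted*
(pre-transform), so counts are mode-independent and synonymous DNA
sequences stay distinct rows.

For mirror-image campaigns the ranked L-peptide sequences correspond to
D-peptide binders of the natural target; the sequence arithmetic is
identical and no special handling is needed.

## Counting and normalization

Counts are multiplicities of exact DNA strings. The ppm denominator is
the round's total of frame-valid extracted inserts — not total reads
and not total anchor matches — because those inserts are exactly the
stored rows; this makes Σppm = 10⁶ exact per round and the ppm values
of different rounds directly comparable. ppm is stored at full float64
precision; any rounding is presentation-only.

## Scoring

With f(s, R) the ppm of sequence s in round R:

* enrichment score = f(s, final target round) / f(s, naive library)
* empty score = f(s, final target round) / f(s, final empty round)

One record is produced per sequence present in the final target round;
earlier target-round ppm values are reported as context columns only.
Records are sorted by empty score descending, with a complete tie-break
chain (enrichment score desc, final-target ppm desc, lexicographic DNA)
so the ranking is a total order and byte-identical across runs and
input read orders.

**Denominator floor.** The ratios are undefined when a sequence is
absent from a control round. A floor of 0.5 ppm (half the smallest
frequency observable at the 10⁶ scale; configurable) replaces zero
denominators, so "never observed in a control" ranks strongest instead
of being dropped. Consequence worth knowing: at low sequencing depth a
rare target-round sequence absent from the empty round can receive a
large floored empty score — its ceiling is (target ppm)/0.5, i.e.
2·10⁶/reads per observed read — so empty-round depth comparable to the
target round is advisable.

**Direct control.** No published formula exists for the direct control
(target selection continued one round without target); inventing a hard
rule seemed worse than exposing the data. The ratio
f(s, direct)/max(f(s, target 3), floor) is reported as a column, and an
optional maximum-ratio filter is available but off by default.
Filtering (minimum target ppm, minimum enrichment score, maximum
direct-control ratio) is applied after scoring and ordering.

## Persistence

One SQLite file per campaign: one table per selection round, a rounds
registry (name, user, totals, ISO-8601 date), saved anchor patterns,
and an evaluation table. Round tables are written once and never
touched by evaluation, so the original extracted data survive any
re-filtering; this is asserted by checksumming round tables across
evaluation in the tests. Table names derive from the selection name by
replacing non-alphanumerics with underscores.

## Synthetic campaigns

The simulator generates the full file set a campaign provides — target
rounds 1..k, matched empty rounds, a direct control, the naive library —
plus a manifest with the true multiplicity of every insert and the
identity of every corrupted read.

Model: the library holds n distinct random inserts with Zipf-distributed
abundances (exponent 1.1 by default), the characteristic skew of real
phage libraries. A planted binder's weight is multiplied by its
enrichment factor once per target round; weights evolve
deterministically and are renormalized, and each round's reads are one
multinomial draw from that round's weight vector — the simplest model
consistent with panning-plus-amplification resampling. Empty rounds
draw from the un-boosted background; the direct control carries the
advantage through round k−1 plus one neutral round. Each read is
random-pad + left anchor + insert + right anchor + random-pad (pad
lengths uniform in 5–15 nt), quality constant `I`.

Two corruption types are planted, each read receiving at most one: an
anchor point mutation (rate `anchor_mutation_rate`) and a 1-nt deletion
inside the insert (rate `frameshift_rate`). Generation rejection-samples
so the ground truth is exact rather than statistical: library inserts
and pads never contain spurious anchor occurrences, a mutated read is
redrawn until it no longer matches the exact pattern, and a deleted
read is redrawn until extraction yields the length-(L−1) insert. Under
a fixed seed the FASTQ output is byte-identical and manifest counts
equal extraction outcomes exactly (misses = planted SNVs, frame
failures = planted frameshifts, tallies = clean multiplicities).

What the simulator does not emulate: substitution errors inside the
insert, quality-correlated errors, indels other than single deletions,
PCR chimeras, and biophysical binding kinetics. Passing tests therefore
demonstrate the correctness of the bookkeeping and ranking machinery,
not robustness to every real-data artifact; on real data, insert-level
sequencing errors will inflate the tail of singleton sequences.

## Default parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| translation mode | forward | — | no transform unless the construct requires one |
| ppm floor | 0.5 | ppm | half the smallest observable frequency at 10⁶ scale |
| direct-control filter | off | — | no published criterion; expose, don't invent |
| stop-codon handling | keep, render `*` | — | frame check is the only discard rule |
| Zipf exponent | 1.1 | — | library-skew magnitude typical of naive phage libraries |
| binder advantage | 10 | ×/round | well-separated from background for recovery studies |
| reads per round | 50,000 | reads | deep enough that every library member is expected ≥ several times |
| library size | 1,000 | sequences | insert diversity at 1:50 depth ratio |
| corruption rates | 0.05 / 0.02 | fraction | few-percent anchor SNV and indel rates |
| pad length | 5–15 | nt | short flanking vector context around the amplicon |

Test and verification problem sizes: unit tests run campaigns of
100–300 library sequences at 1,000–10,000 reads/round; the end-to-end
binder-recovery check runs 1,000 sequences at 50,000 reads/round over
three rounds and three seeds; the extraction oracle runs on 10,000
randomized reads. The whole suite completes in about a minute on one
core.

## Known limitations

* Anchor matching tolerates zero mismatches by design; the variant
  re-search handles single substitutions only (no anchor indels).
* No reverse-complement fallback search of the read: if the construct
  is sequenced in mixed orientations, the minority orientation is
  missed (the translation modes handle a uniformly flipped read-out,
  not per-read mixtures).
* Wrapped (multi-line) FASTQ and paired-end merging are unsupported;
  input is strict 4-line FASTQ, optionally gzipped.
* No statistical testing of enrichment (no p-values); scores are
  descriptive ratios, and depth imbalance between target and control
  rounds shifts the floored-score ceiling noted above.
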