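# phagerank

Control-aware enrichment analysis of phage-display selections sequenced
by NGS.

## The problem

Phage display (and mirror-image phage display) enriches peptide binders
over successive rounds of panning against a target. Deep sequencing of
each round yields millions of amplicon reads, but the experimenter only
cares about the randomized insert between two constant vector sequences
("framing anchors"), and raw enrichment alone is misleading: clones with
amplification advantages or plastic-binding behaviour enrich without any
target affinity. `phagerank` extracts the insert from every read, counts
sequences at the DNA level, normalizes per round, and ranks candidates
against three kinds of control selections.

## The method

For each read, the insert is the substring between the first occurrence
of the left anchor and the nearest following occurrence of the right
anchor (non-greedy, at most one insert per read — equivalent to the
pattern `LEFT(.+?)RIGHT`). Inserts whose length is not divisible by 3
carry a frame-breaking indel and are set aside; the rest are translated
(four read-out modes: forward, forward complement, reverse, reverse
complement; standard genetic code, stops as `*`, ambiguous codons as
`X`). Counts are per distinct DNA sequence and normalized to parts per
million of the round's frame-valid inserts, so Σppm = 10⁶ per round and
rounds of different depth are comparable.

With *f(s, R)* the ppm frequency of sequence *s* in round *R*:

    enrichment score(s) = f(s, target round 3) / f(s, naive library)
    empty score(s)      = f(s, target round 3) / f(s, empty-selection round 3)

The **empty score** is the primary ranking key: a sequence that also
enriches in a target-free selection is target-independent and scores
near 1. A zero control frequency is floored at 0.5 ppm (configurable) so
"never seen in a control" ranks strongest instead of dividing by zero. A
**direct control** (target selection continued one round without target)
is reported as a ratio column and can optionally be used as a filter.

Reads whose anchors carry a point mutation are missed by exact matching;
they can be re-searched with every single-substitution anchor variant
(`variants` command) and reported separately.

## Worked example

Simulate a ground-truthed campaign (5 planted binders with a 10× per-
round advantage among 1,000 library sequences), analyze it, and rank:

```
phagerank simulate --out-dir demo --seed 1 --n-library 1000 \
    --reads-per-round 50000 --rounds 3 --n-binders 5 --factor 10
phagerank extract --db demo/campaign.db \
    --left-anchor GATTCCAGG --right-anchor TACGACCCG --mode forward \
    --role target1=demo/target_1.fastq --role target2=demo/target_2.fastq \
    --role target3=demo/target_3.fastq --role empty3=demo/empty_3.fastq \
    --role library=demo/library.fastq
phagerank score --db demo/campaign.db --out demo/evaluation.tsv
```

`extract` prints one line per round, e.g.

```
target3: 50000 reads, 50000 counted, 0 without anchor match, incomplete-sequence frequency 0.0000%
```

and `score` prints `scored 952 sequences -> demo/evaluation.tsv`. The
TSV is ordered by empty score, descending; the top five rows are exactly
the five planted binders (seed 1, first columns shown, values truncated):

```
rank  dna                          empty_score  enrichment_score  target3_ppm
1     CGTTAATTACTCCTCCGGAATTTG...  843.3        361.4              50600.0
2     GTTAGTCCTGGGGTTAAGTAGTTT...  603.0        301.5              36180.0
3     TCGACTCGCACGCTCGTTCAGGTC...  426.2       1065.5              42620.0
4     CACAATGTTTCCGCTATGCGCTTC...  383.3        523.5             429300.0
5     TACACTACCTAGCATACCCATGTA...  351.9        312.8              56300.0
```

An empty score of 843 means the sequence is 843× more frequent in target
round 3 than in the matched target-free round — strong evidence of
target-dependent enrichment; background sequences score near 1.

## Database schema

One SQLite file per campaign: a `rounds` registry
(`selection_name, table_name, user, total_counted, frame_fail_count,
processed_date`), one table per round (`round_<name>`: `dna, peptide,
raw_count, ppm`), a `patterns` table of saved anchor pairs, and an
`evaluation` table (`rank, dna, peptide, empty_score, enrichment_score,
per-round ppm columns`). Round tables are never modified by evaluation,
so results can be re-filtered at any time; any SQLite client can query
the file directly.

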