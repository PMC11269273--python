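import random

import pytest

from phagerank.quantify import CountTable, build_count_table, normalize_ppm
from phagerank.scoring import (
    RoundSet,
    ScoringConfig,
    ScoringConfigError,
    empty_score,
    enrichment_score,
    evaluate,
    evaluation_frame,
)


def table_from_ppm(name, ppm_map, total=1_000_000):
    """Build a CountTable whose ppm values equal *ppm_map* exactly."""
    counts = {
        dna: ("P" * (len(dna) // 3), round(ppm * total / 1_000_000))
        for dna, ppm in ppm_map.items()
    }
    filler = total - sum(n for _, n in counts.values())
    counts[FILLER] = ("GGG", filler)
    return CountTable(name, normalize_ppm(counts, total), total)


FILLER = "GGGGGGGGG"  # bulk sequence absorbing the rest of each round


def strip_filler(records):
    return [r for r in records if r.dna != FILLER]


class TestScoreFormulas:
    def test_enrichment_ratio(self):
        assert enrichment_score(200.0, 4.0, 0.5) == pytest.approx(50.0)

    def test_absent_from_target(self):
        assert enrichment_score(0.0, 4.0, 0.5) == 0.0

    def test_enrichment_floor_on_zero_library(self):
        assert enrichment_score(200.0, 0.0, 0.5) == pytest.approx(400.0)

    def test_empty_ratio(self):
        assert empty_score(200.0, 10.0, 0.5) == pytest.approx(20.0)

    def test_no_depletion_equals_one(self):
        assert empty_score(50.0, 50.0, 0.5) == pytest.approx(1.0)

    def test_empty_floor_on_zero_control(self):
        assert empty_score(200.0, 0.0, 0.5) == pytest.approx(400.0)

    @pytest.mark.parametrize("bad_floor", [0.0, -1.0])
    def test_floor_must_be_positive(self, bad_floor):
        with pytest.raises(ScoringConfigError):
            enrichment_score(1.0, 1.0, bad_floor)
        with pytest.raises(ScoringConfigError):
            ScoringConfig(floor_ppm=bad_floor)


class TestEvaluate:
    def rounds(self):
        target3 = table_from_ppm(
            "target3", {"AAATTTGGG": 200.0, "CCCTTTGGG": 100.0, "TTTTTTTTT": 50.0}
        )
        empty3 = table_from_ppm("empty3", {"AAATTTGGG": 10.0, "CCCTTTGGG": 20.0})
        library = table_from_ppm("library", {"AAATTTGGG": 4.0, "CCCTTTGGG": 4.0})
        return RoundSet(targets=[target3], empties=[empty3], library=library)

    def test_ordered_by_empty_score_descending(self):
        records = evaluate(self.rounds())
        scores = [r.empty_score for r in records]
        assert scores == sorted(scores, reverse=True)
        assert records[0].dna == "TTTTTTTTT"  # absent from both controls
        assert records[1].dna == "AAATTTGGG"

    def test_floored_absences_rank_strongest(self):
        records = evaluate(self.rounds())
        top = records[0]
        assert top.library_ppm == 0.0 and top.empty3_ppm == 0.0
        assert top.empty_score == pytest.approx(top.target3_ppm / 0.5)

    def test_missing_library_is_a_config_error(self):
        rounds = self.rounds()
        rounds.library = None
        with pytest.raises(ScoringConfigError, match="library"):
            evaluate(rounds)

    def test_missing_empty_round_is_a_config_error(self):
        rounds = self.rounds()
        rounds.empties = []
        with pytest.raises(ScoringConfigError, match="empty"):
            evaluate(rounds)

    def test_tie_broken_by_enrichment_score(self):
        # same empty score (both floored), different library ppm
        target3 = table_from_ppm("t3", {"AAAAAAAAA": 200.0, "CCCCCCCCC": 200.0})
        empty3 = table_from_ppm("e3", {})
        library = table_from_ppm("lib", {"AAAAAAAAA": 4.0})
        records = evaluate(
            RoundSet(targets=[target3], empties=[empty3], library=library)
        )
        assert records[0].dna == "CCCCCCCCC"  # enrichment 400 beats 50
        assert records[0].enrichment_score > records[1].enrichment_score

    def test_filters_applied_after_scoring(self):
        config = ScoringConfig(min_target_ppm=80.0)
        records = strip_filler(evaluate(self.rounds(), config))
        assert {r.dna for r in records} == {"AAATTTGGG", "CCCTTTGGG"}
        config = ScoringConfig(min_enrichment_score=30.0)
        records = evaluate(self.rounds(), config)
        assert all(r.enrichment_score >= 30.0 for r in records)

    def test_direct_control_ratio_reported_not_filtered_by_default(self):
        rounds = self.rounds()
        rounds.direct_control = table_from_ppm("direct", {"AAATTTGGG": 400.0})
        records = strip_filler(evaluate(rounds))
        by_dna = {r.dna: r for r in records}
        assert by_dna["AAATTTGGG"].direct_control_ratio == pytest.approx(2.0)
        assert len(records) == 3  # nothing dropped
        strict = ScoringConfig(max_direct_control_ratio=1.0)
        filtered = evaluate(rounds, strict)
        assert "AAATTTGGG" not in {r.dna for r in filtered}

    def test_earlier_target_rounds_reported_as_context(self):
        t1 = table_from_ppm("t1", {"AAATTTGGG": 10.0})
        t2 = table_from_ppm("t2", {"AAATTTGGG": 50.0})
        t3 = table_from_ppm("t3", {"AAATTTGGG": 200.0})
        e3 = table_from_ppm("e3", {"AAATTTGGG": 10.0})
        lib = table_from_ppm("lib", {"AAATTTGGG": 4.0})
        records = evaluate(
            RoundSet(targets=[t1, t2, t3], empties=[e3], library=lib)
        )
        top = records[0]
        assert top.target1_ppm == pytest.approx(10.0)
        assert top.target2_ppm == pytest.approx(50.0)


def test_scale_invariance_of_scores(clean_campaign):
    """Multiplying every raw count of one round by a constant must leave
    all scores unchanged (ppm normalization)."""
    spec, manifest = clean_campaign
    truth = {
        name: manifest.rounds[name].multiplicities
        for name in ("target_3", "empty_3", "library")
    }

    def build(mult):
        def tab(name, m):
            pairs = [
                (dna, "") for dna, n in truth[name].items() for _ in range(n * m)
            ]
            return build_count_table(pairs, name)

        return RoundSet(
            targets=[tab("target_3", mult)],
            empties=[tab("empty_3", 1)],
            library=[tab("library", 1)][0],
        )

    base = evaluate(build(1))
    tripled = evaluate(build(3))
    assert [(r.dna, r.empty_score, r.enrichment_score) for r in base] == [
        (r.dna, r.empty_score, r.enrichment_score) for r in tripled
    ]


def test_ranking_invariant_under_input_permutation(small_campaign):
    """Permuting read order never changes the evaluation table."""
    from phagerank.extraction import extract_round
    from phagerank.translation import translate_round

    spec, manifest = small_campaign

    def build(shuffle_seed=None):
        tables = {}
        for name in ("target_3", "empty_3", "library"):
            records = list(manifest.records_by_round[name])
            if shuffle_seed is not None:
                random.Random(shuffle_seed).shuffle(records)
            result = extract_round(records, spec.pattern)
            pairs = translate_round(result.inserts, "forward")
            tables[name] = build_count_table(pairs, name)
        return RoundSet(
            targets=[tables["target_3"]],
            empties=[tables["empty_3"]],
            library=tables["library"],
        )

    baseline = evaluation_frame(evaluate(build()))
    for seed in (1, 2):
        permuted = evaluation_frame(evaluate(build(seed)))
        assert permuted.equals(baseline)
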