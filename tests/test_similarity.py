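"""BLAST hit filtering and composite similarity scoring."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rescue_rank.errors import ConfigurationError, DomainError
from rescue_rank.similarity import (
    BlastHit,
    FilterCriteria,
    SimilarityWeights,
    filter_hits,
    overall_score,
    paralog_penalty,
    parse_blast_table,
    rank_hits,
    score_hits,
    sequence_similarity,
    taxonomic_similarity,
)
from rescue_rank.taxonomy import RankPenaltySchedule, TaxonomicDistance


def make_hit(subject_id="S1", pident=50.0, evalue=1e-10, qcov=90.0, bitscore=200.0, taxon=6):
    return BlastHit(
        query_id="Q",
        subject_id=subject_id,
        pident=pident,
        evalue=evalue,
        qcov=qcov,
        bitscore=bitscore,
        subject_taxon=taxon,
    )


ROW = "Q\tS1_A\t45.2\t270\t148\t1\t1\t270\t1\t270\t1.5e-30\t250.1\t90.0\t6"


class TestParseBlastTable:
    def test_single_well_formed_row(self):
        hits = parse_blast_table(ROW + "\n")
        assert len(hits) == 1
        h = hits[0]
        assert h.subject_id == "S1_A"
        assert h.pident == 45.2
        assert h.evalue == 1.5e-30
        assert h.qcov == 90.0
        assert h.subject_taxon == 6

    def test_malformed_row_skipped_with_warning(self, caplog):
        bad = ROW.replace("45.2", "not-a-number")
        with caplog.at_level("WARNING"):
            hits = parse_blast_table(ROW + "\n" + bad + "\n")
        assert len(hits) == 1
        assert any("malformed" in r.message for r in caplog.records)

    def test_generated_row_count_round_trips(self):
        text = "\n".join(ROW.replace("S1_A", f"S{i}_A") for i in range(50))
        assert len(parse_blast_table(text)) == 50

    def test_empty_input_is_empty_list(self):
        assert parse_blast_table("") == []

    def test_missing_required_column_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            parse_blast_table(ROW, columns=("qseqid", "sseqid"))


class TestFilterHits:
    def test_pident_at_19_excluded(self):
        hits = [make_hit(pident=19.0), make_hit(subject_id="S2", pident=21.0)]
        kept = filter_hits(hits)
        assert [h.subject_id for h in kept] == ["S2"]

    def test_pident_exactly_at_threshold_excluded_strict(self):
        assert filter_hits([make_hit(pident=20.0)]) == []

    def test_evalue_1e2_excluded(self):
        assert filter_hits([make_hit(evalue=1e-2)]) == []

    def test_qcov_at_threshold_excluded_strict(self):
        assert filter_hits([make_hit(qcov=75.0)]) == []
        assert len(filter_hits([make_hit(qcov=75.1)])) == 1

    def test_cap_keeps_best_by_bitscore(self):
        hits = [
            make_hit(subject_id=f"S{i:03d}", bitscore=float(i)) for i in range(80)
        ]
        kept = filter_hits(hits)
        assert len(kept) == 50
        assert min(h.bitscore for h in kept) == 30.0

    def test_cap_ties_break_on_evalue_then_subject_id(self):
        hits = [
            make_hit(subject_id="B", bitscore=100.0, evalue=1e-10),
            make_hit(subject_id="A", bitscore=100.0, evalue=1e-10),
            make_hit(subject_id="C", bitscore=100.0, evalue=1e-20),
        ]
        kept = filter_hits(hits, FilterCriteria(max_hits=2))
        assert [h.subject_id for h in kept] == ["C", "A"]

    def test_idempotent(self):
        hits = [make_hit(subject_id=f"S{i}", pident=15 + i) for i in range(30)]
        once = filter_hits(hits)
        twice = filter_hits(once)
        assert once == twice


class TestScoreComponents:
    @pytest.mark.parametrize("pident,expected", [(100.0, 1.0), (0.0, 0.0), (20.0, 0.2)])
    def test_sequence_similarity_linear(self, pident, expected):
        assert sequence_similarity(pident) == pytest.approx(expected)

    def test_sequence_similarity_domain_error(self):
        with pytest.raises(DomainError):
            sequence_similarity(101.0)

    def test_taxonomic_similarity_zero_distance_is_half(self):
        d = TaxonomicDistance(raw_distance=0.0, path=[1])
        assert taxonomic_similarity(d, maxdistance=10.0) == 0.5

    def test_taxonomic_similarity_at_maxdistance_is_zero(self):
        d = TaxonomicDistance(raw_distance=10.0, path=[1, 2])
        assert taxonomic_similarity(d, maxdistance=10.0) == 0.0

    def test_taxonomic_similarity_midpoint(self):
        d = TaxonomicDistance(raw_distance=5.0, path=[1, 2])
        assert taxonomic_similarity(d, maxdistance=10.0) == 0.5

    def test_fallback_steps_subtract_decrement(self):
        d = TaxonomicDistance(raw_distance=5.0, path=[1, 2], fallback_steps=2)
        sched = RankPenaltySchedule(missing_lineage_decrement=0.05)
        assert taxonomic_similarity(d, 10.0, sched) == pytest.approx(0.4)

    def test_clamped_at_zero_beyond_maxdistance(self):
        d = TaxonomicDistance(raw_distance=25.0, path=[1, 2])
        assert taxonomic_similarity(d, maxdistance=10.0) == 0.0

    def test_maxdistance_nonpositive_is_domain_error(self):
        d = TaxonomicDistance(raw_distance=1.0, path=[1, 2])
        with pytest.raises(DomainError):
            taxonomic_similarity(d, maxdistance=0.0)

    @pytest.mark.parametrize(
        "s,same,expected", [(0.5, True, 0.25), (0.5, False, 0.5), (0.0, True, 0.0)]
    )
    def test_paralog_penalty(self, s, same, expected):
        assert paralog_penalty(s, same) == expected

    @pytest.mark.parametrize(
        "s_seq,s_taxa,expected", [(1.0, 1.0, 1.0), (1.0, 0.0, 0.5), (0.2, 0.5, 0.35)]
    )
    def test_overall_score_default_weights(self, s_seq, s_taxa, expected):
        assert overall_score(s_seq, s_taxa) == pytest.approx(expected)

    def test_weights_must_sum_to_one(self):
        with pytest.raises((ConfigurationError, ValueError)):
            SimilarityWeights(w_seq=0.7, w_taxa=0.7)


class TestRankHits:
    def _scored(self, subject_id, s_overall, s_seq=0.5):
        from rescue_rank.similarity import ScoredHit

        return ScoredHit(
            hit=make_hit(subject_id=subject_id),
            s_seq=s_seq,
            s_taxa_raw=0.5,
            s_taxa=0.5,
            s_overall=s_overall,
        )

    def test_threshold_discards_low_scores(self):
        scored = [self._scored("A", 0.9), self._scored("B", 0.4)]
        assert [s.hit.subject_id for s in rank_hits(scored, min_score=0.5)] == ["A"]

    def test_empty_input_empty_output(self):
        assert rank_hits([], min_score=0.5) == []

    def test_top_k_matches_full_sort_oracle(self):
        import random

        rng = random.Random(3)
        scored = [self._scored(f"S{i}", round(rng.random(), 6)) for i in range(10)]
        ranked = rank_hits(scored, min_score=0.0, limit=3)
        oracle = sorted(scored, key=lambda s: (-s.s_overall, -s.s_seq, s.hit.subject_id))[:3]
        assert ranked == oracle

    def test_output_is_subset_permutation_of_input(self):
        scored = [self._scored(f"S{i}", 0.1 * i) for i in range(8)]
        ranked = rank_hits(scored, min_score=0.0, limit=20)
        assert sorted(r.hit.subject_id for r in ranked) == sorted(
            s.hit.subject_id for s in scored
        )


@settings(derandomize=True, max_examples=60)
@given(
    p1=st.floats(min_value=0, max_value=100),
    p2=st.floats(min_value=0, max_value=100),
    s_taxa=st.floats(min_value=0, max_value=1),
)
def test_overall_bounded_and_monotone_in_pident(p1, p2, s_taxa):
    """S_overall stays in [0,1] and never decreases as identity grows."""
    lo, hi = sorted((p1, p2))
    s_lo = overall_score(sequence_similarity(lo), s_taxa)
    s_hi = overall_score(sequence_similarity(hi), s_taxa)
    assert 0.0 <= s_lo <= 1.0 and 0.0 <= s_hi <= 1.0
    assert s_hi >= s_lo


@settings(derandomize=True, max_examples=60)
@given(s_taxa=st.floats(min_value=0, max_value=1), s_seq=st.floats(min_value=0, max_value=1))
def test_paralog_penalty_reduces_overall_by_half_taxa_weight(s_taxa, s_seq):
    """With default weights the paralog penalty costs exactly w_taxa * s_taxa / 2."""
    unpenalized = overall_score(s_seq, s_taxa)
    penalized = overall_score(s_seq, paralog_penalty(s_taxa, True))
    assert penalized <= unpenalized + 1e-12
    assert unpenalized - penalized == pytest.approx(0.5 * s_taxa / 2.0)


def test_score_hits_excludes_unresolvable_organisms(small_tree, caplog):
    hits = [make_hit(subject_id="OK", taxon=7), make_hit(subject_id="GONE", taxon=4242)]
    with caplog.at_level("WARNING"):
        scored = score_hits(hits, small_tree, query_taxon=6)
    assert [s.hit.subject_id for s in scored] == ["OK"]
    assert any("not resolvable" in r.message for r in caplog.records)


def test_score_hits_marks_paralogs(small_tree):
    hits = [make_hit(subject_id="SELF", taxon=6)]
    scored = score_hits(hits, small_tree, query_taxon=6)
    assert scored[0].is_paralog
    assert scored[0].s_taxa == pytest.approx(0.25)  # 0.5 at distance zero, halved
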