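import random

import pytest

from spliceprof.events import (
    EventType,
    collapse_redundant,
    compare_transcript_pair,
    extract_events,
)
from spliceprof.model import TranscriptSet
from spliceprof.oracle import oracle_events

from conftest import mk_transcript, random_gene_transcripts


def as_set(events):
    return {e.event_id for e in events}


class TestPairComparison:
    def test_canonical_exon_skipping(self, skip_pair):
        on, off = skip_pair
        events = compare_transcript_pair(on, off)
        assert len(events) == 1
        ev = events[0]
        assert ev.event_type is EventType.SKIP
        assert ev.target_exons[0].coords() == (201, 300)
        assert ev.flank_intron_left.coords() == (101, 200)
        assert ev.flank_intron_right.coords() == (301, 400)
        assert ev.spanning_intron.coords() == (101, 400)
        assert ev.on_transcripts == {("s", "T_on")}
        assert ev.off_transcripts == {("s", "T_off")}

    def test_identical_structures_yield_no_events(self):
        a = mk_transcript([(1, 100), (201, 300)], tid="A")
        b = mk_transcript([(1, 100), (201, 300)], tid="B")
        assert compare_transcript_pair(a, b) == []

    def test_symmetric_up_to_role_assignment(self, skip_pair):
        on, off = skip_pair
        fwd = compare_transcript_pair(on, off)
        rev = compare_transcript_pair(off, on)
        assert as_set(fwd) == as_set(rev)
        assert fwd[0].on_transcripts == rev[0].on_transcripts

    def test_cassette_requires_two_or_more_skipped_exons(self):
        off = mk_transcript([(1, 100), (801, 900)], tid="A")
        on = mk_transcript(
            [(1, 100), (201, 300), (401, 500), (801, 900)], tid="B"
        )
        (ev,) = compare_transcript_pair(on, off)
        assert ev.event_type is EventType.CASSETTE
        assert [x.coords() for x in ev.target_exons] == [(201, 300), (401, 500)]

    def test_intron_retention_single_and_multi(self):
        spliced = mk_transcript([(1, 100), (201, 300), (401, 500)], tid="S")
        retained = mk_transcript([(1, 300), (401, 500)], tid="R")
        (ev,) = compare_transcript_pair(retained, spliced)
        assert ev.event_type is EventType.IR_single
        assert ev.target_exons[0].coords() == (101, 200)
        assert ev.retention_exon.coords() == (1, 300)
        assert ev.on_transcripts == {("s", "R")}

        both = mk_transcript([(1, 500)], tid="R2")
        (ev2,) = compare_transcript_pair(both, spliced)
        assert ev2.event_type is EventType.IR_multi
        assert [x.coords() for x in ev2.target_exons] == [(101, 200), (301, 400)]

    def test_alternative_start_follows_transcription_direction(self):
        a = mk_transcript([(1, 100), (201, 300)], tid="A", strand="-")
        b = mk_transcript([(51, 100), (201, 300)], tid="B", strand="-")
        (ev,) = compare_transcript_pair(a, b)
        # genomic-left variation on the minus strand is the transcript end
        assert ev.event_type is EventType.ALT_END

    def test_alt_exon_ends_for_internal_exon_only(self):
        a = mk_transcript([(1, 100), (201, 300), (401, 500)], tid="A")
        b = mk_transcript([(1, 100), (201, 280), (401, 500)], tid="B")
        (ev,) = compare_transcript_pair(a, b)
        assert ev.event_type is EventType.ALT_EXON_ENDS
        assert {x.coords() for x in ev.target_exons} == {(201, 300), (201, 280)}
        # the longer variant carries the 'on' role
        assert ev.on_transcripts == {("s", "A")}

    def test_different_chromosome_or_gene_is_an_error(self, skip_pair):
        on, off = skip_pair
        other_chrom = mk_transcript([(1, 100), (401, 500)], chrom="chr2")
        with pytest.raises(ValueError, match="chromosome"):
            compare_transcript_pair(on, other_chrom)
        other_gene = mk_transcript([(1, 100), (401, 500)], gene="G2")
        with pytest.raises(ValueError, match="gene"):
            compare_transcript_pair(on, other_gene)

    def test_agrees_with_brute_force_oracle_on_random_genes(self):
        rng = random.Random(11)
        for _ in range(300):
            ts = random_gene_transcripts(rng)
            for i in range(len(ts)):
                for j in range(i + 1, len(ts)):
                    assert as_set(compare_transcript_pair(ts[i], ts[j])) == as_set(
                        oracle_events(ts[i], ts[j])
                    )


class TestExtraction:
    def _three_isoform_set(self):
        ts = TranscriptSet(sample_id="s")
        ts.add(mk_transcript([(1, 100), (401, 500)], tid="T1", fpkm=1.0))
        ts.add(
            mk_transcript([(1, 100), (201, 300), (401, 500)], tid="T2", fpkm=1.0)
        )
        ts.add(
            mk_transcript([(1, 100), (201, 300), (401, 500), (601, 700)],
                          tid="T3", fpkm=1.0)
        )
        return ts

    def test_identical_coordinate_events_merge_supporters(self):
        catalog = extract_events(self._three_isoform_set())
        skips = [e for e in catalog if e.event_type is EventType.SKIP]
        assert len(skips) == 1
        assert skips[0].off_transcripts == {("s", "T1")}
        assert skips[0].on_transcripts == {("s", "T2"), ("s", "T3")}
        assert skips[0].within_sample

    def test_low_expression_genes_are_excluded(self):
        ts = TranscriptSet(sample_id="s")
        ts.add(mk_transcript([(1, 100), (401, 500)], tid="T1", fpkm=0.03))
        ts.add(
            mk_transcript([(1, 100), (201, 300), (401, 500)], tid="T2", fpkm=0.02)
        )
        assert len(extract_events(ts, gene_fpkm_min=0.1)) == 0
        assert len(extract_events(ts, gene_fpkm_min=0.05)) == 1

    def test_pair_comparison_count_is_n_choose_2(self):
        rng = random.Random(5)
        ts = TranscriptSet(sample_id="s")
        for i, t in enumerate(random_gene_transcripts(rng, max_transcripts=6)):
            t.transcript_id = f"T{i}"
            ts.add(t)
        n = len(ts)
        catalog = extract_events(ts)
        assert catalog.n_pair_comparisons == n * (n - 1) // 2

    def test_output_invariant_under_input_permutation(self):
        rng = random.Random(13)
        transcripts = random_gene_transcripts(rng, max_transcripts=6)
        ts1 = TranscriptSet(sample_id="s")
        for t in transcripts:
            ts1.add(t)
        ts2 = TranscriptSet(sample_id="s")
        for t in reversed(transcripts):
            ts2.add(t)
        assert set(extract_events(ts1).events) == set(extract_events(ts2).events)

    def test_empty_input_gives_empty_catalog(self):
        assert len(extract_events(TranscriptSet(sample_id="s"))) == 0


class TestRedundancyCollapse:
    def _catalog_with_jittered_pair(self, shift):
        ts = TranscriptSet(sample_id="s")
        ts.add(mk_transcript([(1, 100), (401, 500)], tid="T1"))
        ts.add(mk_transcript([(1, 100), (201, 300), (401, 500)], tid="T2"))
        # a shifted copy of the same skipping structure, in its own gene so
        # only the wobble relation (not pair comparison) links the events
        ts.add(mk_transcript([(1, 100), (401, 500)], tid="T3", gene="G2"))
        ts.add(
            mk_transcript(
                [(1, 100), (201 + shift, 300), (401, 500)], tid="T4", gene="G2"
            )
        )
        return extract_events(ts)

    def test_within_wobble_events_form_one_cluster(self):
        catalog = self._catalog_with_jittered_pair(shift=2)
        collapsed, report = collapse_redundant(catalog, wobble=5)
        assert report.n_events == 2
        assert report.cluster_sizes == [2]
        assert report.n_redundant == 1
        assert len(collapsed) == 1

    def test_beyond_wobble_events_stay_separate(self):
        catalog = self._catalog_with_jittered_pair(shift=6)
        collapsed, report = collapse_redundant(catalog, wobble=5)
        assert report.n_redundant == 0
        assert len(collapsed) == 2

    def test_collapse_is_idempotent(self):
        rng = random.Random(3)
        ts = TranscriptSet(sample_id="s")
        for g in range(5):
            for i, t in enumerate(random_gene_transcripts(rng, gene=f"G{g}")):
                t.transcript_id = f"G{g}.T{i}"
                t.gene_id = f"G{g}"
                ts.add(t)
        catalog = extract_events(ts)
        once, _ = collapse_redundant(catalog, wobble=5)
        twice, rep2 = collapse_redundant(once, wobble=5)
        assert set(once.events) == set(twice.events)
        assert rep2.n_redundant == 0

    def test_jittered_clusters_recover_true_structure(self):
        # plant clusters by shifting one boundary of a known skip by <=wobble
        rng = random.Random(9)
        ts = TranscriptSet(sample_id="s")
        n_clusters = 6
        for c in range(n_clusters):
            base = 10_000 * (c + 1)
            for rep in range(3):
                d = rng.randint(0, 2)  # all pairwise diffs <= 4 <= wobble
                tid = f"C{c}R{rep}"
                ts.add(
                    mk_transcript(
                        [(base, base + 99 + d), (base + 400, base + 499)],
                        tid=tid + "off", gene=f"G{c}",
                    )
                )
                ts.add(
                    mk_transcript(
                        [
                            (base, base + 99 + d),
                            (base + 200 + d, base + 299),
                            (base + 400, base + 499),
                        ],
                        tid=tid + "on", gene=f"G{c}",
                    )
                )
        catalog = extract_events(ts)
        collapsed, report = collapse_redundant(catalog, wobble=5)
        assert report.n_clusters == n_clusters
        assert len(collapsed) == n_clusters
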