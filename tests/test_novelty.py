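import random

import pytest

from spliceprof.events import extract_events
from spliceprof.model import GenomicInterval, TranscriptSet
from spliceprof.novelty import (
    AnnotationIndex,
    classify_novelty,
    event_exon_features,
    event_intron_features,
    match_feature,
    read_bed12_introns,
    tissue_occurrence_bins,
)

from conftest import mk_transcript


def iv(start, end, chrom="chr1", strand="+"):
    return GenomicInterval(chrom, start, end, strand)


class TestMatchFeature:
    def test_small_endpoint_deviations_match(self):
        idx = AnnotationIndex.from_features(exons=[iv(103, 198)])
        assert match_feature(iv(100, 200), idx, "exon", W=5) == iv(103, 198)

    def test_deviation_beyond_tolerance_does_not_match(self):
        idx = AnnotationIndex.from_features(exons=[iv(106, 200)])
        assert match_feature(iv(100, 200), idx, "exon", W=5) is None

    def test_minimal_total_deviation_wins(self):
        idx = AnnotationIndex.from_features(exons=[iv(103, 203), iv(101, 199)])
        assert match_feature(iv(100, 200), idx, "exon", W=5) == iv(101, 199)

    def test_strands_must_agree_when_both_known(self):
        idx = AnnotationIndex.from_features(exons=[iv(100, 200, strand="-")])
        assert match_feature(iv(100, 200, strand="+"), idx, "exon", 5) is None
        assert match_feature(iv(100, 200, strand="."), idx, "exon", 5) is not None

    def test_agrees_with_exhaustive_scan(self):
        rng = random.Random(21)
        feats = [
            iv(s, s + rng.randint(20, 200))
            for s in (rng.randint(1, 50_000) for _ in range(300))
        ]
        idx = AnnotationIndex.from_features(exons=feats)
        for _ in range(300):
            base = rng.choice(feats)
            q = iv(
                base.start + rng.randint(-8, 8), base.end + rng.randint(-8, 8)
            )
            W = rng.randint(0, 6)
            got = match_feature(q, idx, "exon", W)
            hits = [
                f
                for f in feats
                if abs(f.start - q.start) <= W and abs(f.end - q.end) <= W
            ]
            if not hits:
                assert got is None
            else:
                best = min(
                    hits,
                    key=lambda f: (
                        abs(f.start - q.start) + abs(f.end - q.end),
                        (f.start, f.end),
                    ),
                )
                assert got == best

    def test_known_set_grows_monotonically_with_tolerance(self):
        rng = random.Random(4)
        truth = [iv(s, s + 100) for s in range(1000, 20_000, 500)]
        jittered = [
            iv(f.start + rng.randint(-5, 5), f.end + rng.randint(-5, 5))
            for f in truth
        ]
        idx = AnnotationIndex.from_features(exons=jittered)
        prev = set()
        for W in range(0, 11):
            known = {
                f.coords() for f in truth if match_feature(f, idx, "exon", W)
            }
            assert prev <= known
            prev = known
        assert prev == {f.coords() for f in truth}  # all matched at W >= jitter


def build_skip_catalog():
    ts = TranscriptSet(sample_id="s")
    ts.add(mk_transcript([(1, 100), (401, 500)], tid="T1"))
    ts.add(mk_transcript([(1, 100), (201, 300), (401, 500)], tid="T2"))
    return extract_events(ts)


class TestClassifyNovelty:
    def test_known_in_any_single_source_suffices(self):
        catalog = build_skip_catalog()
        (ev,) = list(catalog)
        on = mk_transcript([(1, 100), (201, 300), (401, 500)], tid="A1")
        off = mk_transcript([(1, 100), (401, 500)], tid="A2")
        full = AnnotationIndex.from_features(
            exons=[e for t in (on, off) for e in t.exons],
            introns=[i for t in (on, off) for i in t.introns()],
        )
        empty = AnnotationIndex.from_features(exons=[iv(90_000, 90_100)])
        lab = classify_novelty(ev, [empty, full], W=5)
        assert (lab.exon_status, lab.intron_status) == ("known", "known")
        assert lab.event_status == "known"

    def test_unannotated_spanning_intron_makes_the_event_novel(self):
        catalog = build_skip_catalog()
        (ev,) = list(catalog)
        on_only = mk_transcript([(1, 100), (201, 300), (401, 500)], tid="A1")
        idx = AnnotationIndex.from_features(
            exons=list(on_only.exons), introns=list(on_only.introns())
        )
        lab = classify_novelty(ev, [idx], W=5)
        assert lab.exon_status == "known"
        assert lab.intron_status == "novel"
        assert lab.event_status == "novel"

    def test_overlap_distinguishes_boundary_novelty_from_new_exons(self):
        catalog = build_skip_catalog()
        (ev,) = list(catalog)
        # shifted exon: overlaps the target exon but beyond W at one end
        near = AnnotationIndex.from_features(exons=[iv(231, 300)])
        lab = classify_novelty(ev, [near], W=5)
        assert lab.exon_status == "novel_overlapping"
        far = AnnotationIndex.from_features(exons=[iv(90_000, 90_100)])
        lab2 = classify_novelty(ev, [far], W=5)
        assert lab2.exon_status == "novel_nonoverlapping"

    def test_adding_a_source_never_increases_novelty(self):
        catalog = build_skip_catalog()
        (ev,) = list(catalog)
        partial = AnnotationIndex.from_features(exons=[iv(201, 300)])
        extra = AnnotationIndex.from_features(
            introns=[iv(101, 200), iv(301, 400), iv(101, 400)]
        )
        lab1 = classify_novelty(ev, [partial], W=5)
        lab2 = classify_novelty(ev, [partial, extra], W=5)
        rank = {"known": 0, "novel": 1}
        assert rank[lab2.event_status] <= rank[lab1.event_status]
        assert lab2.event_status == "known"

    def test_event_known_implies_all_components_known(self):
        rng = random.Random(17)
        from conftest import random_gene_transcripts

        for trial in range(30):
            ts = TranscriptSet(sample_id="s")
            for i, t in enumerate(random_gene_transcripts(rng)):
                t.transcript_id = f"T{i}"
                ts.add(t)
            catalog = extract_events(ts)
            idx = AnnotationIndex.from_features(
                exons=[e for t in ts for e in t.exons],
                introns=[i for t in ts for i in t.introns()],
            )
            for ev in catalog:
                lab = classify_novelty(ev, [idx], W=0)
                if lab.event_status == "known":
                    assert lab.exon_status == "known"
                    assert lab.intron_status == "known"


class TestOccurrenceBins:
    def test_feature_bins_count_supporting_samples(self):
        sets = []
        for s in ("A", "B", "C", "D"):
            ts = TranscriptSet(sample_id=s)
            ts.add(mk_transcript([(1, 100), (401, 500)], tid="T1", sample=s))
            if s in ("A", "B", "C"):
                ts.add(
                    mk_transcript(
                        [(1, 100), (201, 300), (401, 500)], tid="T2", sample=s
                    )
                )
            sets.append(ts)
        catalog = extract_events(sets)
        bins = tissue_occurrence_bins(catalog, "exon")
        row = bins[bins["n_samples"] == 3]
        assert int(row["count"].iloc[0]) == 1  # the skipped exon: 3 samples
        ibins = tissue_occurrence_bins(catalog, "intron")
        # spanning intron seen in all 4 samples (off form everywhere)
        assert int(ibins[ibins["n_samples"] == 4]["count"].iloc[0]) == 1

    def test_planted_occupancy_distribution_recovered_exactly(self):
        rng = random.Random(31)
        samples = [f"s{i}" for i in range(6)]
        planted = {}
        sets = {s: TranscriptSet(sample_id=s) for s in samples}
        for g in range(20):
            base = 10_000 * (g + 1)
            exons_on = [(base, base + 99), (base + 200, base + 299), (base + 400, base + 499)]
            exons_off = [(base, base + 99), (base + 400, base + 499)]
            k = rng.randint(1, len(samples))
            chosen = rng.sample(samples, k)
            for s in samples:
                sets[s].add(
                    mk_transcript(exons_off, tid=f"G{g}off", gene=f"G{g}", sample=s)
                )
                if s in chosen:
                    sets[s].add(
                        mk_transcript(exons_on, tid=f"G{g}on", gene=f"G{g}", sample=s)
                    )
            planted[(base + 200, base + 299)] = k
        catalog = extract_events(list(sets.values()))
        bins = tissue_occurrence_bins(catalog, "exon")
        expected = {}
        for k in planted.values():
            expected[k] = expected.get(k, 0) + 1
        got = dict(zip(bins["n_samples"], bins["count"]))
        assert got == expected


def test_bed12_blocks_become_exons_and_gap_introns():
    bed = "chr1\t99\t500\tEST1\t0\t+\t99\t500\t0\t2\t101,100\t0,301\n"
    idx = read_bed12_introns(bed)
    assert match_feature(iv(100, 200), idx, "exon", W=0) is not None
    assert match_feature(iv(201, 400), idx, "intron", W=0) is not None
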