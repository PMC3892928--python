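import random

import pytest

from spliceprof.model import GenomicInterval, Transcript


def mk_transcript(exons, tid="T", gene="G", sample="s", strand="+", fpkm=None,
                  chrom="chr1"):
    return Transcript(
        transcript_id=tid,
        gene_id=gene,
        sample_id=sample,
        exons=[GenomicInterval(chrom, a, b, strand) for a, b in exons],
        fpkm=fpkm,
    )


def random_gene_transcripts(rng: random.Random, max_transcripts=6, max_exons=10,
                            gene="G", chrom="chr1"):
    """Random isoforms over a shared exon grid: subsets of exons, occasional
    adjacent-exon merges (retention-like) and boundary shifts. All transcripts
    are valid and share gene/chrom so every pair is comparable."""
    n = max_exons
    cur = rng.randint(1, 1000)
    base = []
    for _ in range(n):
        ln = rng.randint(50, 200)
        base.append((cur, cur + ln - 1))
        cur = cur + ln + rng.randint(50, 300)
    strand = rng.choice("+-.")
    out = []
    for t in range(rng.randint(2, max_transcripts)):
        k = rng.randint(2, n)
        idx = sorted(rng.sample(range(n), k))
        exons = [list(base[i]) for i in idx]
        if rng.random() < 0.4 and len(exons) >= 2:
            j = rng.randrange(len(exons) - 1)
            exons[j] = [exons[j][0], exons[j + 1][1]]
            del exons[j + 1]
        if rng.random() < 0.4:
            j = rng.randrange(len(exons))
            side = rng.choice([0, 1])
            val = exons[j][side] + rng.randint(1, 30) * rng.choice([-1, 1])
            lo = exons[j - 1][1] + 2 if j else 0
            hi = exons[j + 1][0] - 2 if j < len(exons) - 1 else 10 ** 9
            if side == 0 and lo < val < exons[j][1]:
                exons[j][0] = val
            elif side == 1 and exons[j][0] < val < hi:
                exons[j][1] = val
        out.append(
            mk_transcript(
                [tuple(e) for e in exons],
                tid=f"T{t}",
                gene=gene,
                strand=strand,
                chrom=chrom,
            )
        )
    return out


@pytest.fixture
def skip_pair():
    """The canonical exon-skipping configuration: T_on carries the middle
    exon, T_off joins the flanks with a single spanning intron."""
    off = mk_transcript([(1, 100), (401, 500)], tid="T_off")
    on = mk_transcript([(1, 100), (201, 300), (401, 500)], tid="T_on")
    return on, off
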