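"""Reference event classifier used only in tests.

``oracle_events`` re-derives the events distinguishing a transcript pair by
exhaustive enumeration over all exon runs, exon/intron correspondences and
chain alignments — deliberately a different strategy from the production
scanner in :mod:`spliceprof.events`, which it cross-checks. Definitions of
the event classes are shared (they must be); the code is not.
"""

from __future__ import annotations

from .events import ASEvent, EventType
from .model import GenomicInterval, Transcript

__all__ = ["oracle_events"]


def _roles_by_longer(va, ta, vb, tb):
    if (va.length, -va.start) > (vb.length, -vb.start):
        return {ta.key()}, {tb.key()}
    return {tb.key()}, {ta.key()}


def _enumerate_skipping(on: Transcript, off: Transcript, strand: str) -> list[ASEvent]:
    """Every run of >=1 consecutive internal exons of ``on`` whose flanking
    introns' outer boundaries form an intron of ``off``."""
    found = []
    introns_on = on.introns()
    off_intron_set = {iv.coords() for iv in off.introns()}
    n = len(on.exons)
    for i in range(1, n - 1):
        for j in range(i, n - 1):
            left = introns_on[i - 1]
            right = introns_on[j]
            if (left.start, right.end) not in off_intron_set:
                continue
            targets = tuple(on.exons[i : j + 1])
            found.append(
                ASEvent(
                    event_type=(
                        EventType.SKIP if len(targets) == 1 else EventType.CASSETTE
                    ),
                    chrom=on.chrom,
                    strand=strand,
                    gene_id=on.gene_id,
                    target_exons=targets,
                    flank_intron_left=left,
                    flank_intron_right=right,
                    spanning_intron=GenomicInterval(
                        on.chrom, left.start, right.end, strand
                    ),
                    on_transcripts={on.key()},
                    off_transcripts={off.key()},
                )
            )
    return found


def _enumerate_retention(ret: Transcript, spl: Transcript, strand: str) -> list[ASEvent]:
    found = []
    introns_spl = spl.introns()
    for exon in ret.exons:
        for i in range(len(spl.exons)):
            for j in range(i + 1, len(spl.exons)):
                if spl.exons[i].start == exon.start and spl.exons[j].end == exon.end:
                    retained = tuple(introns_spl[i:j])
                    found.append(
                        ASEvent(
                            event_type=(
                                EventType.IR_single
                                if len(retained) == 1
                                else EventType.IR_multi
                            ),
                            chrom=ret.chrom,
                            strand=strand,
                            gene_id=ret.gene_id,
                            target_exons=retained,
                            retention_exon=exon,
                            on_transcripts={ret.key()},
                            off_transcripts={spl.key()},
                        )
                    )
    return found


def _enumerate_alt(a: Transcript, b: Transcript, strand: str) -> list[ASEvent]:
    """Flattened-endpoint comparison of the two intron chains: the chains
    may differ at no endpoint (terminal-exon outer boundaries can still
    move) or at exactly one endpoint, which maps back to one exon
    boundary."""
    found = []
    ia, ib = a.introns(), b.introns()
    if len(ia) != len(ib):
        return found
    n = len(a.exons)
    ea = [x for iv in ia for x in (iv.start, iv.end)]
    eb = [x for iv in ib for x in (iv.start, iv.end)]
    diffs = [p for p, (x, y) in enumerate(zip(ea, eb)) if x != y]
    last = 2 * len(ia) - 1

    def _terminal(exon_a, exon_b, genomic_left: bool) -> ASEvent:
        if genomic_left:
            etype = EventType.ALT_END if strand == "-" else EventType.ALT_START
        else:
            etype = EventType.ALT_START if strand == "-" else EventType.ALT_END
        on, off = _roles_by_longer(exon_a, a, exon_b, b)
        return ASEvent(
            event_type=etype,
            chrom=a.chrom,
            strand=strand,
            gene_id=a.gene_id,
            target_exons=tuple(sorted([exon_a, exon_b])),
            on_transcripts=on,
            off_transcripts=off,
        )

    if diffs in ([], [0]) and a.exons[0].start != b.exons[0].start:
        found.append(_terminal(a.exons[0], b.exons[0], genomic_left=True))
    if diffs in ([], [last]) and a.exons[-1].end != b.exons[-1].end:
        found.append(_terminal(a.exons[-1], b.exons[-1], genomic_left=False))

    if len(diffs) == 1:
        p = diffs[0]
        # even p: intron p//2 start moved, i.e. exon p//2 3' boundary;
        # odd p: intron p//2 end moved, i.e. exon p//2+1 5' boundary
        idx = p // 2 if p % 2 == 0 else p // 2 + 1
        if 1 <= idx <= n - 2:
            va, vb = a.exons[idx], b.exons[idx]
            on, off = _roles_by_longer(va, a, vb, b)
            found.append(
                ASEvent(
                    event_type=EventType.ALT_EXON_ENDS,
                    chrom=a.chrom,
                    strand=strand,
                    gene_id=a.gene_id,
                    target_exons=tuple(sorted([va, vb])),
                    on_transcripts=on,
                    off_transcripts=off,
                )
            )
    return found


def oracle_events(a: Transcript, b: Transcript) -> list[ASEvent]:
    """Brute-force enumeration of all events between two transcripts."""
    if a.chrom != b.chrom:
        raise ValueError("different chromosomes")
    if a.gene_id != b.gene_id:
        raise ValueError("different genes")
    strand = a.strand if a.strand == b.strand else "."
    events: list[ASEvent] = []
    if a.is_multi_exon and b.is_multi_exon:
        events += _enumerate_skipping(b, a, strand)
        events += _enumerate_skipping(a, b, strand)
        events += _enumerate_alt(a, b, strand)
    if b.is_multi_exon:
        events += _enumerate_retention(a, b, strand)
    if a.is_multi_exon:
        events += _enumerate_retention(b, a, strand)
    return events
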