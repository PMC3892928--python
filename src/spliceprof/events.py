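"""Alternative-splicing event discovery from transcript pairs.

Every unordered pair of transcripts within a gene is compared and each
exon/intron structure difference is emitted as a typed event:

* ``SKIP`` — one internal exon present in the 'on' form and absent from the
  'off' form, whose single intron spans the exon plus both flanking introns;
  the flanking intron boundaries must match the spanning intron exactly.
* ``CASSETTE`` — two or more consecutive exons jointly skipped within one
  spanning intron (same flank-matching rule).
* ``IR_single`` / ``IR_multi`` — one exon of the retaining ('on') form
  exactly covers an exon-intron-...-exon span of the spliced ('off') form,
  retaining one or several consecutive introns.
* ``ALT_START`` / ``ALT_END`` — the terminal exon at the transcription
  start (end) differs while the remainder of the intron chain is identical.
* ``ALT_EXON_ENDS`` — one internal exon shares one boundary and differs at
  the other, the intron chains being otherwise identical.

Events with identical type and coordinates found in different pairs are a
single catalog entry whose on/off supporter sets accumulate. Near-redundant
entries (all boundaries within a small wobble, caused by imprecise spliced
alignment) are reported and optionally collapsed separately — event
identity itself is always exact-coordinate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Sequence

from .model import GenomicInterval, Transcript, TranscriptSet

__all__ = [
    "EventType",
    "ASEvent",
    "EventCatalog",
    "RedundancyReport",
    "compare_transcript_pair",
    "extract_events",
    "collapse_redundant",
]


class EventType(str, Enum):
    SKIP = "SKIP"
    CASSETTE = "CASSETTE"
    IR_single = "IR_single"
    IR_multi = "IR_multi"
    ALT_START = "ALT_START"
    ALT_END = "ALT_END"
    ALT_EXON_ENDS = "ALT_EXON_ENDS"


# event types with no flanking/spanning intron structure
_TERMINAL_TYPES = {EventType.ALT_START, EventType.ALT_END, EventType.ALT_EXON_ENDS}


@dataclass
class ASEvent:
    """A typed splicing difference between an 'on' and an 'off' form.

    ``target_exons`` holds the defining feature(s): the skipped exon(s) for
    SKIP/CASSETTE, the retained intron(s) for IR, and the two variant exons
    for the ALT types. ``retention_exon`` is the covering exon of the IR
    'on' form. Supporter sets are ``(sample_id, transcript_id)`` pairs.
    """

    event_type: EventType
    chrom: str
    strand: str
    gene_id: str
    target_exons: tuple[GenomicInterval, ...]
    flank_intron_left: GenomicInterval | None = None
    flank_intron_right: GenomicInterval | None = None
    spanning_intron: GenomicInterval | None = None
    retention_exon: GenomicInterval | None = None
    on_transcripts: set[tuple[str, str]] = field(default_factory=set)
    off_transcripts: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.event_type in (EventType.SKIP, EventType.CASSETTE):
            assert self.flank_intron_left and self.flank_intron_right
            assert self.spanning_intron
            assert self.spanning_intron.start == self.flank_intron_left.start
            assert self.spanning_intron.end == self.flank_intron_right.end
            n = len(self.target_exons)
            assert (n == 1) == (self.event_type is EventType.SKIP)
        if self.event_type in (EventType.IR_single, EventType.IR_multi):
            assert self.retention_exon is not None
            n = len(self.target_exons)
            assert (n == 1) == (self.event_type is EventType.IR_single)

    def coordinates(self) -> tuple[tuple[int, int], ...]:
        """All defining intervals, in a fixed order — the event's identity."""
        parts: list[tuple[int, int]] = [e.coords() for e in self.target_exons]
        for iv in (
            self.flank_intron_left,
            self.flank_intron_right,
            self.spanning_intron,
            self.retention_exon,
        ):
            if iv is not None:
                parts.append(iv.coords())
        return tuple(parts)

    @property
    def event_id(self) -> str:
        coords = ",".join(f"{s}-{e}" for s, e in self.coordinates())
        return f"{self.event_type.value}:{self.chrom}:{self.strand}:{coords}"

    @property
    def n_on(self) -> int:
        return len(self.on_transcripts)

    @property
    def n_off(self) -> int:
        return len(self.off_transcripts)

    @property
    def samples(self) -> set[str]:
        return {s for s, _ in self.on_transcripts | self.off_transcripts}

    @property
    def within_sample(self) -> bool:
        """True if some single sample carries both forms of the event."""
        on = {s for s, _ in self.on_transcripts}
        off = {s for s, _ in self.off_transcripts}
        return bool(on & off)


def _event_strand(a: Transcript, b: Transcript) -> str:
    return a.strand if a.strand == b.strand else "."


def _skip_cassette(on: Transcript, off: Transcript, strand: str) -> Iterator[ASEvent]:
    """Exon skipping / cassette: scan each intron of the candidate 'off' form."""
    on_introns = on.introns()
    start_at = {iv.start: k for k, iv in enumerate(on_introns)}
    end_at = {iv.end: k for k, iv in enumerate(on_introns)}
    for spanning in off.introns():
        j = start_at.get(spanning.start)
        j2 = end_at.get(spanning.end)
        if j is None or j2 is None or j2 <= j:
            continue
        targets = tuple(on.exons[j + 1 : j2 + 1])
        etype = EventType.SKIP if len(targets) == 1 else EventType.CASSETTE
        yield ASEvent(
            event_type=etype,
            chrom=on.chrom,
            strand=strand,
            gene_id=on.gene_id,
            target_exons=targets,
            flank_intron_left=on_introns[j],
            flank_intron_right=on_introns[j2],
            spanning_intron=spanning,
            on_transcripts={on.key()},
            off_transcripts={off.key()},
        )


def _intron_retention(ret: Transcript, spl: Transcript, strand: str) -> Iterator[ASEvent]:
    """Intron retention: an exon of ``ret`` covering exon...exon of ``spl``."""
    start_at = {e.start: k for k, e in enumerate(spl.exons)}
    end_at = {e.end: k for k, e in enumerate(spl.exons)}
    introns = spl.introns()
    for exon in ret.exons:
        i = start_at.get(exon.start)
        j = end_at.get(exon.end)
        if i is None or j is None or j <= i:
            continue
        retained = tuple(introns[i:j])
        etype = EventType.IR_single if len(retained) == 1 else EventType.IR_multi
        yield ASEvent(
            event_type=etype,
            chrom=ret.chrom,
            strand=strand,
            gene_id=ret.gene_id,
            target_exons=retained,
            retention_exon=exon,
            on_transcripts={ret.key()},
            off_transcripts={spl.key()},
        )


def _variant_pair_roles(
    va: GenomicInterval, a: Transcript, vb: GenomicInterval, b: Transcript
) -> tuple[set[tuple[str, str]], set[tuple[str, str]]]:
    """on = form with the longer variant exon; ties by smaller start."""
    if (va.length, -va.start) > (vb.length, -vb.start):
        return {a.key()}, {b.key()}
    return {b.key()}, {a.key()}


def _alt_terminal(a: Transcript, b: Transcript, strand: str) -> Iterator[ASEvent]:
    """Alternative transcript start/end: terminal exon differs at its outer
    boundary, the rest of the intron chain identical; labels follow
    transcription direction on '-' strand, genomic left otherwise."""
    ia, ib = a.introns(), b.introns()
    if len(ia) != len(ib):
        return
    # genomic-left variation
    if (
        ia[1:] == ib[1:]
        and ia[0].end == ib[0].end
        and a.exons[0].start != b.exons[0].start
    ):
        etype = EventType.ALT_END if strand == "-" else EventType.ALT_START
        on, off = _variant_pair_roles(a.exons[0], a, b.exons[0], b)
        yield ASEvent(
            event_type=etype,
            chrom=a.chrom,
            strand=strand,
            gene_id=a.gene_id,
            target_exons=tuple(sorted([a.exons[0], b.exons[0]])),
            on_transcripts=on,
            off_transcripts=off,
        )
    # genomic-right variation
    if (
        ia[:-1] == ib[:-1]
        and ia[-1].start == ib[-1].start
        and a.exons[-1].end != b.exons[-1].end
    ):
        etype = EventType.ALT_START if strand == "-" else EventType.ALT_END
        on, off = _variant_pair_roles(a.exons[-1], a, b.exons[-1], b)
        yield ASEvent(
            event_type=etype,
            chrom=a.chrom,
            strand=strand,
            gene_id=a.gene_id,
            target_exons=tuple(sorted([a.exons[-1], b.exons[-1]])),
            on_transcripts=on,
            off_transcripts=off,
        )


def _alt_exon_ends(a: Transcript, b: Transcript, strand: str) -> Iterator[ASEvent]:
    """Alternative ends of one internal exon: intron chains identical except
    a single endpoint of a single intron."""
    ia, ib = a.introns(), b.introns()
    if len(ia) != len(ib):
        return
    diffs = [k for k, (x, y) in enumerate(zip(ia, ib)) if x != y]
    if len(diffs) != 1:
        return
    k = diffs[0]
    n_exons = len(a.exons)
    if ia[k].end == ib[k].end and ia[k].start != ib[k].start:
        exon_idx = k  # exon upstream of intron k has a different 3' boundary
    elif ia[k].start == ib[k].start and ia[k].end != ib[k].end:
        exon_idx = k + 1
    else:
        return  # both endpoints differ: not a single-boundary variation
    if not (1 <= exon_idx <= n_exons - 2):
        return  # terminal exon: outside this class
    va, vb = a.exons[exon_idx], b.exons[exon_idx]
    on, off = _variant_pair_roles(va, a, vb, b)
    yield ASEvent(
        event_type=EventType.ALT_EXON_ENDS,
        chrom=a.chrom,
        strand=strand,
        gene_id=a.gene_id,
        target_exons=tuple(sorted([va, vb])),
        on_transcripts=on,
        off_transcripts=off,
    )


def compare_transcript_pair(a: Transcript, b: Transcript) -> list[ASEvent]:
    """All splicing events distinguishing two transcripts of one gene.

    Symmetric in argument order up to on/off role assignment; identical
    structures yield no events. Raises ``ValueError`` when the transcripts
    are on different chromosomes or belong to different genes.
    """
    if a.chrom != b.chrom:
        raise ValueError(
            f"transcripts {a.transcript_id}/{b.transcript_id} are on different "
            f"chromosomes ({a.chrom} vs {b.chrom})"
        )
    if a.gene_id != b.gene_id:
        raise ValueError(
            f"transcripts {a.transcript_id}/{b.transcript_id} belong to "
            f"different genes ({a.gene_id} vs {b.gene_id})"
        )
    strand = _event_strand(a, b)
    events: list[ASEvent] = []
    if a.is_multi_exon and b.is_multi_exon:
        events.extend(_skip_cassette(on=b, off=a, strand=strand))
        events.extend(_skip_cassette(on=a, off=b, strand=strand))
        events.extend(_alt_terminal(a, b, strand))
        events.extend(_alt_exon_ends(a, b, strand))
    if b.is_multi_exon:
        events.extend(_intron_retention(ret=a, spl=b, strand=strand))
    if a.is_multi_exon:
        events.extend(_intron_retention(ret=b, spl=a, strand=strand))
    return events


@dataclass
class EventCatalog:
    """Deduplicated event collection with per-pair provenance."""

    events: dict[str, ASEvent] = field(default_factory=dict)
    provenance: dict[str, list[tuple[tuple[str, str], tuple[str, str]]]] = field(
        default_factory=dict
    )
    n_pair_comparisons: int = 0

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[ASEvent]:
        return iter(self.events.values())

    def __contains__(self, event_id: str) -> bool:
        return event_id in self.events

    def add(
        self,
        event: ASEvent,
        pair: tuple[tuple[str, str], tuple[str, str]] | None = None,
    ) -> None:
        existing = self.events.get(event.event_id)
        if existing is None:
            self.events[event.event_id] = event
        else:
            existing.on_transcripts |= event.on_transcripts
            existing.off_transcripts |= event.off_transcripts
        if pair is not None:
            self.provenance.setdefault(event.event_id, []).append(pair)

    def by_type(self) -> dict[EventType, list[ASEvent]]:
        out: dict[EventType, list[ASEvent]] = {}
        for ev in self:
            out.setdefault(ev.event_type, []).append(ev)
        return out


def _gene_passes_fpkm(transcripts: Sequence[Transcript], gene_fpkm_min: float) -> bool:
    """Gene-level expression filter: the summed transcript FPKM must reach
    the cutoff in at least one sample. Genes whose transcripts carry no
    FPKM at all (unquantified input) are not filtered."""
    if all(t.fpkm is None for t in transcripts):
        return True
    per_sample: dict[str, float] = {}
    for t in transcripts:
        per_sample[t.sample_id] = per_sample.get(t.sample_id, 0.0) + (t.fpkm or 0.0)
    return any(total >= gene_fpkm_min for total in per_sample.values())


def extract_events(
    samples: TranscriptSet | Iterable[TranscriptSet],
    gene_fpkm_min: float = 0.1,
) -> EventCatalog:
    """Build the event catalog over one or several samples ('extract-as').

    Transcripts are pooled across samples (gene names must already be
    reconciled across them) and all unordered transcript pairs within each
    sufficiently expressed gene are compared. Identical events merge into a
    single entry; supporters accumulate. Empty input yields an empty catalog.
    """
    if isinstance(samples, TranscriptSet):
        samples = [samples]
    genes: dict[str, list[Transcript]] = {}
    for ts in samples:
        for t in ts:
            genes.setdefault(t.gene_id, []).append(t)

    catalog = EventCatalog()
    for gene_id in sorted(genes):
        transcripts = genes[gene_id]
        if not _gene_passes_fpkm(transcripts, gene_fpkm_min):
            continue
        for a, b in itertools.combinations(transcripts, 2):
            catalog.n_pair_comparisons += 1
            for ev in compare_transcript_pair(a, b):
                catalog.add(ev, pair=(a.key(), b.key()))
    return catalog


@dataclass
class RedundancyReport:
    """Summary of near-redundant (boundary-wobble) event clusters."""

    wobble: int
    n_events: int
    n_clusters: int
    cluster_sizes: list[int]
    n_redundant: int

    @property
    def redundant_fraction(self) -> float:
        return self.n_redundant / self.n_events if self.n_events else 0.0


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _within_wobble(
    ca: tuple[tuple[int, int], ...], cb: tuple[tuple[int, int], ...], wobble: int
) -> bool:
    return all(
        abs(sa - sb) <= wobble and abs(ea - eb) <= wobble
        for (sa, ea), (sb, eb) in zip(ca, cb)
    )


def collapse_redundant(
    catalog: EventCatalog, wobble: int = 5
) -> tuple[EventCatalog, RedundancyReport]:
    """Cluster same-type events whose every boundary agrees within ``wobble``
    base pairs and keep one representative per cluster.

    Clustering is single-linkage (transitive closure of the pairwise
    relation); the representative is the event with the most supporting
    transcripts, ties broken by smallest coordinates. The report counts the
    non-representative events as redundant.
    """
    if wobble < 0:
        raise ValueError("wobble must be >= 0")
    groups: dict[tuple, list[ASEvent]] = {}
    for ev in catalog:
        key = (ev.event_type, ev.chrom, ev.strand, len(ev.coordinates()))
        groups.setdefault(key, []).append(ev)

    collapsed = EventCatalog(n_pair_comparisons=catalog.n_pair_comparisons)
    cluster_sizes: list[int] = []
    for key in sorted(groups, key=str):
        members = sorted(groups[key], key=lambda e: e.coordinates())
        coords = [e.coordinates() for e in members]
        uf = _UnionFind(len(members))
        for i, j in itertools.combinations(range(len(members)), 2):
            if _within_wobble(coords[i], coords[j], wobble):
                uf.union(i, j)
        clusters: dict[int, list[ASEvent]] = {}
        for i, ev in enumerate(members):
            clusters.setdefault(uf.find(i), []).append(ev)
        for root in sorted(clusters):
            cluster = clusters[root]
            cluster_sizes.append(len(cluster))
            rep = min(
                cluster, key=lambda e: (-(e.n_on + e.n_off), e.coordinates())
            )
            collapsed.add(rep)
            for pair in catalog.provenance.get(rep.event_id, []):
                collapsed.provenance.setdefault(rep.event_id, []).append(pair)

    n_events = len(catalog)
    report = RedundancyReport(
        wobble=wobble,
        n_events=n_events,
        n_clusters=len(cluster_sizes),
        cluster_sizes=sorted(cluster_sizes, reverse=True),
        n_redundant=n_events - len(cluster_sizes),
    )
    return collapsed, report
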