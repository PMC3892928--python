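"""Known/novel classification of events against reference annotations.

A feature (exon or intron) is *known* when some annotation source contains
a feature of the same kind on the same chromosome whose two endpoints each
lie within a tolerance W of the query's (W = 5 bp by default, absorbing
small splice-boundary ambiguities across annotation releases). An event is
known only when its defining exon(s) and all of its defining introns are
known; otherwise the label records whether the novelty comes from the exon
side, the intron side, or both, and whether a novel exon at least overlaps
an annotated one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Mapping

import pandas as pd
from intervaltree import IntervalTree

from .events import ASEvent, EventCatalog, EventType
from .model import GenomicInterval, TranscriptSet, parse_gtf

__all__ = [
    "AnnotationIndex",
    "NoveltyLabel",
    "match_feature",
    "classify_novelty",
    "event_exon_features",
    "event_intron_features",
    "feature_sample_occurrence",
    "tissue_occurrence_bins",
    "read_bed12_introns",
]


class AnnotationIndex:
    """Read-only interval index of annotated exons and introns.

    Introns are derived from each annotated transcript's exon chain, so a
    plain transcript GTF (Ensembl-style or any other dialect the reader
    accepts) is sufficient input.
    """

    def __init__(self, source_name: str = "annotation") -> None:
        self.source_name = source_name
        self._trees: dict[tuple[str, str], IntervalTree] = {}

    @classmethod
    def from_gtf(
        cls, source: str | IO[str], source_name: str = "annotation"
    ) -> "AnnotationIndex":
        ts = parse_gtf(source, sample_id=source_name)
        return cls.from_transcript_set(ts, source_name=source_name)

    @classmethod
    def from_transcript_set(
        cls, ts: TranscriptSet, source_name: str = "annotation"
    ) -> "AnnotationIndex":
        idx = cls(source_name)
        for t in ts:
            for e in t.exons:
                idx._insert("exon", e)
            for i in t.introns():
                idx._insert("intron", i)
        return idx

    @classmethod
    def from_features(
        cls,
        exons: Iterable[GenomicInterval] = (),
        introns: Iterable[GenomicInterval] = (),
        source_name: str = "annotation",
    ) -> "AnnotationIndex":
        idx = cls(source_name)
        for e in exons:
            idx._insert("exon", e)
        for i in introns:
            idx._insert("intron", i)
        return idx

    def _insert(self, kind: str, iv: GenomicInterval) -> None:
        tree = self._trees.setdefault((kind, iv.chrom), IntervalTree())
        # closed genomic coordinates -> half-open tree keys
        tree.addi(iv.start, iv.end + 1, iv)

    def candidates(
        self, kind: str, f: GenomicInterval, pad: int = 0
    ) -> list[GenomicInterval]:
        tree = self._trees.get((kind, f.chrom))
        if tree is None:
            return []
        return [hit.data for hit in tree.overlap(f.start - pad, f.end + 1 + pad)]

    def overlaps_any(self, kind: str, f: GenomicInterval) -> bool:
        """>=1 bp genomic overlap with any annotated feature of this kind,
        strand-agnostic when either strand is unknown."""
        for cand in self.candidates(kind, f):
            if f.strand == "." or cand.strand == "." or f.strand == cand.strand:
                return True
        return False


def match_feature(
    f: GenomicInterval, idx: AnnotationIndex, kind: str, W: int = 5
) -> GenomicInterval | None:
    """Best annotated feature matching ``f`` within endpoint tolerance W.

    A candidate matches when it is the same kind, on the same chromosome,
    strands agree whenever both are known, and both |Δstart| and |Δend| are
    at most W. Among matches the one with minimal total endpoint deviation
    is returned (ties to the smallest coordinates); None when nothing
    matches.
    """
    if W < 0:
        raise ValueError("tolerance W must be >= 0")
    best: tuple[int, tuple[int, int]] | None = None
    best_feat: GenomicInterval | None = None
    for cand in idx.candidates(kind, f, pad=W):
        if f.strand != "." and cand.strand != "." and f.strand != cand.strand:
            continue
        ds, de = abs(cand.start - f.start), abs(cand.end - f.end)
        if ds > W or de > W:
            continue
        score = (ds + de, (cand.start, cand.end))
        if best is None or score < best:
            best = score
            best_feat = cand
    return best_feat


def event_exon_features(e: ASEvent) -> tuple[GenomicInterval, ...]:
    """The exon features that define an event (checked for exon novelty)."""
    if e.event_type in (EventType.IR_single, EventType.IR_multi):
        assert e.retention_exon is not None
        return (e.retention_exon,)
    return e.target_exons


def event_intron_features(e: ASEvent) -> tuple[GenomicInterval, ...]:
    """The intron features that define an event: flanking and spanning
    introns for skipping-type events, the retained introns for IR."""
    if e.event_type in (EventType.SKIP, EventType.CASSETTE):
        assert e.flank_intron_left and e.flank_intron_right and e.spanning_intron
        return (e.flank_intron_left, e.flank_intron_right, e.spanning_intron)
    if e.event_type in (EventType.IR_single, EventType.IR_multi):
        return e.target_exons  # retained introns
    return ()


@dataclass(frozen=True)
class NoveltyLabel:
    """Decomposed known/novel status of one event.

    ``exon_status``: known | novel_overlapping | novel_nonoverlapping;
    ``intron_status``: known | novel; ``event_status`` is known iff both
    component statuses are known.
    """

    exon_status: str
    intron_status: str

    @property
    def event_status(self) -> str:
        if self.exon_status == "known" and self.intron_status == "known":
            return "known"
        return "novel"


def classify_novelty(
    e: ASEvent, sources: list[AnnotationIndex], W: int = 5
) -> NoveltyLabel:
    """Label an event against one or more annotation sources.

    A feature is known if matched in ANY source (union semantics). A novel
    exon that still overlaps some annotated exon by >=1 bp is
    'novel_overlapping' (only its boundaries are new); one overlapping
    nothing is 'novel_nonoverlapping'.
    """
    if not sources:
        raise ValueError("at least one annotation source is required")

    unmatched_exons = [
        f
        for f in event_exon_features(e)
        if not any(match_feature(f, idx, "exon", W) for idx in sources)
    ]
    if not unmatched_exons:
        exon_status = "known"
    elif all(
        any(idx.overlaps_any("exon", f) for idx in sources) for f in unmatched_exons
    ):
        exon_status = "novel_overlapping"
    else:
        exon_status = "novel_nonoverlapping"

    introns_known = all(
        any(match_feature(f, idx, "intron", W) for idx in sources)
        for f in event_intron_features(e)
    )
    return NoveltyLabel(
        exon_status=exon_status,
        intron_status="known" if introns_known else "novel",
    )


def feature_sample_occurrence(
    catalog: EventCatalog, feature_kind: str
) -> dict[GenomicInterval, set[str]]:
    """Samples in which each distinct event-defining feature was observed.

    A feature counts as observed in a sample when that sample contributes a
    supporting transcript for the form that carries the feature: the 'on'
    form for target/retention exons and flanking introns, the 'off' form
    for spanning and retained introns.
    """
    if feature_kind not in ("exon", "intron"):
        raise ValueError("feature_kind must be 'exon' or 'intron'")
    occ: dict[GenomicInterval, set[str]] = {}

    def _seen(f: GenomicInterval, samples: Iterable[str]) -> None:
        occ.setdefault(f, set()).update(samples)

    for ev in catalog:
        on_samples = {s for s, _ in ev.on_transcripts}
        off_samples = {s for s, _ in ev.off_transcripts}
        if feature_kind == "exon":
            for f in event_exon_features(ev):
                if ev.event_type in (
                    EventType.ALT_START,
                    EventType.ALT_END,
                    EventType.ALT_EXON_ENDS,
                ):
                    _seen(f, on_samples | off_samples)
                else:
                    _seen(f, on_samples)
        else:
            if ev.event_type in (EventType.SKIP, EventType.CASSETTE):
                assert ev.flank_intron_left and ev.flank_intron_right
                _seen(ev.flank_intron_left, on_samples)
                _seen(ev.flank_intron_right, on_samples)
                assert ev.spanning_intron is not None
                _seen(ev.spanning_intron, off_samples)
            elif ev.event_type in (EventType.IR_single, EventType.IR_multi):
                for f in ev.target_exons:  # retained introns: in the spliced form
                    _seen(f, off_samples)
    return occ


def tissue_occurrence_bins(
    catalog: EventCatalog,
    feature_kind: str,
    labels: Mapping[GenomicInterval, str] | None = None,
) -> pd.DataFrame:
    """Bin event features by the number of samples they occur in.

    Returns a tidy frame with columns ``n_samples`` and ``count`` (and
    ``status`` when per-feature novelty labels are supplied), one row per
    occupied bin (or bin x status combination).
    """
    occ = feature_sample_occurrence(catalog, feature_kind)
    rows = []
    for feat, samples in occ.items():
        row = {"n_samples": len(samples)}
        if labels is not None:
            row["status"] = labels.get(feat, "unlabelled")
        rows.append(row)
    if not rows:
        cols = ["n_samples"] + (["status"] if labels is not None else [])
        return pd.DataFrame(columns=cols + ["count"])
    df = pd.DataFrame(rows)
    keys = ["n_samples"] + (["status"] if labels is not None else [])
    out = df.groupby(keys).size().reset_index(name="count")
    return out.sort_values(keys).reset_index(drop=True)


def read_bed12_introns(
    source: str | IO[str], source_name: str = "est"
) -> AnnotationIndex:
    """Build an annotation index from BED12 spliced alignments (e.g. EST
    evidence): block structure gives exons, inter-block gaps give introns.

    BED is 0-based half-open; coordinates are converted to the package's
    1-based inclusive convention.
    """
    import io as _io

    if isinstance(source, str):
        stream: IO[str] = (
            _io.StringIO(source) if "\t" in source or "\n" in source else open(source)
        )
    else:
        stream = source
    exons: list[GenomicInterval] = []
    introns: list[GenomicInterval] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        cols = line.split("\t")
        if len(cols) < 12:
            raise ValueError(f"line {lineno}: BED12 requires 12 columns")
        chrom, chrom_start = cols[0], int(cols[1])
        strand = cols[5] if cols[5] in ("+", "-") else "."
        sizes = [int(x) for x in cols[10].rstrip(",").split(",")]
        starts = [int(x) for x in cols[11].rstrip(",").split(",")]
        blocks = [
            GenomicInterval(chrom, chrom_start + st + 1, chrom_start + st + sz, strand)
            for st, sz in zip(starts, sizes)
        ]
        exons.extend(blocks)
        introns.extend(
            GenomicInterval(chrom, a.end + 1, b.start - 1, strand)
            for a, b in zip(blocks, blocks[1:])
        )
    return AnnotationIndex.from_features(exons, introns, source_name=source_name)
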