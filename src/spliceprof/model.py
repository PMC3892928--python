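"""Transcript models and GTF input/output.

Coordinates are 1-based and inclusive at both ends throughout the package,
the convention of GTF itself: an exon written as ``101 200`` has length 100.
Transcripts are ordered exon chains; introns are the gaps between
consecutive exons and are derived, never stored.

Attribute parsing accepts both the Cufflinks dialect (``FPKM "3.2";``) and
the unquoted Ensembl style; parsing is delegated to :mod:`gffutils`.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import IO, Iterator, Mapping

from gffutils.feature import feature_from_line

STRANDS = ("+", "-", ".")

__all__ = [
    "GenomicInterval",
    "Transcript",
    "TranscriptSet",
    "GtfParseError",
    "TranscriptValidationError",
    "parse_gtf",
    "write_gtf",
    "introns_of",
]


class GtfParseError(ValueError):
    """A GTF line could not be parsed; the message names the line number."""


class TranscriptValidationError(ValueError):
    """Exon structure violates the transcript invariants."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed genomic interval [start, end] on one chromosome.

    ``strand`` is '+', '-' or '.' (unknown); unstranded assemblies carry '.'.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise TranscriptValidationError(
                f"interval start {self.start} > end {self.end} on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise TranscriptValidationError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def coords(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class Transcript:
    """An assembled transcript: an ordered, non-overlapping exon chain.

    ``fpkm`` is the expression level as given by the assembler; ``None``
    means the attribute was absent from the GTF (distinct from 0).
    Single-exon transcripts are valid but flagged (``is_multi_exon``) —
    event discovery only considers multi-exon structures.
    """

    transcript_id: str
    gene_id: str
    sample_id: str
    exons: list[GenomicInterval]
    fpkm: float | None = None

    def __post_init__(self) -> None:
        if not self.exons:
            raise TranscriptValidationError(
                f"transcript {self.transcript_id} has no exons"
            )
        self.exons = sorted(self.exons, key=lambda e: (e.start, e.end))
        chroms = {e.chrom for e in self.exons}
        if len(chroms) != 1:
            raise TranscriptValidationError(
                f"transcript {self.transcript_id} spans chromosomes {sorted(chroms)}"
            )
        strands = {e.strand for e in self.exons}
        if len(strands) != 1:
            raise TranscriptValidationError(
                f"transcript {self.transcript_id} mixes strands {sorted(strands)}"
            )
        for prev, cur in zip(self.exons, self.exons[1:]):
            if cur.start <= prev.end + 1:
                # adjacency (gap of 0) is also invalid: there must be an intron
                raise TranscriptValidationError(
                    f"transcript {self.transcript_id}: exons "
                    f"({prev.start},{prev.end}) and ({cur.start},{cur.end}) "
                    "overlap or are not separated by an intron"
                )
        if self.fpkm is not None and self.fpkm < 0:
            raise TranscriptValidationError(
                f"transcript {self.transcript_id}: negative FPKM {self.fpkm}"
            )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def is_multi_exon(self) -> bool:
        return len(self.exons) > 1

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    def introns(self) -> list[GenomicInterval]:
        return introns_of(self)

    def key(self) -> tuple[str, str]:
        return (self.sample_id, self.transcript_id)


def introns_of(t: Transcript) -> list[GenomicInterval]:
    """Introns of a transcript: the inter-exon gaps, in genomic order.

    For n exons there are n-1 introns; a single-exon transcript has none.
    Intron k is (exon_k.end + 1, exon_{k+1}.start - 1), inclusive.
    """
    return [
        GenomicInterval(a.chrom, a.end + 1, b.start - 1, a.strand)
        for a, b in zip(t.exons, t.exons[1:])
    ]


@dataclass
class TranscriptSet:
    """All transcripts of one sample, grouped by gene."""

    sample_id: str
    transcripts: dict[str, Transcript] = field(default_factory=dict)

    def add(self, t: Transcript) -> None:
        if t.transcript_id in self.transcripts:
            raise TranscriptValidationError(
                f"duplicate transcript_id {t.transcript_id!r} in sample "
                f"{self.sample_id!r}"
            )
        self.transcripts[t.transcript_id] = t

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self) -> Iterator[Transcript]:
        return iter(self.transcripts.values())

    def by_gene(self) -> dict[str, list[Transcript]]:
        genes: dict[str, list[Transcript]] = {}
        for t in self.transcripts.values():
            genes.setdefault(t.gene_id, []).append(t)
        return genes


def _as_stream(source: str | IO[str]) -> IO[str]:
    if isinstance(source, str):
        if "\t" in source or "\n" in source:
            return io.StringIO(source)
        return open(source, "rt")
    return source


def parse_gtf(
    source: str | IO[str],
    sample_id: str,
    chrom_aliases: Mapping[str, str] | None = None,
) -> TranscriptSet:
    """Read a GTF into a :class:`TranscriptSet` for one sample.

    Only ``exon`` feature lines are used; every exon line must carry
    ``gene_id`` and ``transcript_id`` attributes. An ``FPKM`` attribute, if
    present on any exon of a transcript, sets the transcript's expression.
    ``source`` may be a path, an open text stream, or GTF text itself.

    ``chrom_aliases`` optionally maps chromosome names at read time (e.g.
    ``{"1": "chr1"}``); names are otherwise compared as exact strings.

    Raises :class:`GtfParseError` naming the offending line number on a
    malformed line, and :class:`TranscriptValidationError` when assembled
    exon chains violate the transcript invariants.
    """
    aliases = dict(chrom_aliases or {})
    exons: dict[str, list[GenomicInterval]] = {}
    gene_of: dict[str, str] = {}
    fpkm_of: dict[str, float] = {}
    order: list[str] = []

    stream = _as_stream(source)
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        if line.count("\t") != 8:
            raise GtfParseError(
                f"line {lineno}: expected 9 tab-delimited columns, got "
                f"{line.count(chr(9)) + 1}"
            )
        try:
            feat = feature_from_line(line)
        except Exception as exc:  # gffutils raises assorted types
            raise GtfParseError(f"line {lineno}: {exc}") from exc
        if feat.featuretype != "exon":
            continue
        attrs = feat.attributes
        if "gene_id" not in attrs or "transcript_id" not in attrs:
            raise GtfParseError(
                f"line {lineno}: exon feature lacks gene_id/transcript_id"
            )
        tid = attrs["transcript_id"][0]
        gid = attrs["gene_id"][0]
        chrom = aliases.get(feat.seqid, feat.seqid)
        strand = feat.strand if feat.strand in ("+", "-") else "."
        try:
            iv = GenomicInterval(chrom, feat.start, feat.end, strand)
        except TranscriptValidationError as exc:
            raise TranscriptValidationError(f"line {lineno}: {exc}") from exc
        exons.setdefault(tid, []).append(iv)
        if tid not in gene_of:
            gene_of[tid] = gid
            order.append(tid)
        if "FPKM" in attrs:
            fpkm_of[tid] = float(attrs["FPKM"][0])

    ts = TranscriptSet(sample_id=sample_id)
    for tid in order:
        ts.add(
            Transcript(
                transcript_id=tid,
                gene_id=gene_of[tid],
                sample_id=sample_id,
                exons=exons[tid],
                fpkm=fpkm_of.get(tid),
            )
        )
    return ts


def _gtf_lines(ts: TranscriptSet, source: str) -> Iterator[str]:
    for t in ts:
        attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
        if t.fpkm is not None:
            attrs += f' FPKM "{t.fpkm:.6f}";'
        for e in t.exons:
            yield (
                f"{e.chrom}\t{source}\texon\t{e.start}\t{e.end}\t.\t"
                f"{e.strand}\t.\t{attrs}"
            )


def write_gtf(
    ts: TranscriptSet, dest: str | IO[str] | None = None, source: str = "spliceprof"
) -> str | None:
    """Write a TranscriptSet as GTF exon lines (Cufflinks-quoted attributes).

    FPKM is written with 6 decimals; coordinates are written verbatim, so
    ``parse_gtf(write_gtf(ts))`` round-trips exactly at that precision.
    Returns the text when ``dest`` is None.
    """
    text = "\n".join(_gtf_lines(ts, source)) + "\n"
    if dest is None:
        return text
    if isinstance(dest, str):
        with open(dest, "wt") as fh:
            fh.write(text)
        return None
    dest.write(text)
    return None
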