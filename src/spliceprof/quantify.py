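"""Per-sample event quantification ('extract-as-fpkm').

For each event and sample, FPKM_on is the combined FPKM of all isoforms
carrying the exon-containing ('on') form and FPKM_off that of isoforms
carrying the exon-excluding ('off') form. The exon inclusion ratio is

    R = FPKM_on / (FPKM_on + FPKM_off)

and is undefined (not zero) when neither form is expressed, so that
downstream comparison can distinguish an absent event from one expressed
only as the 'off' form. Transcripts are matched to a form with a boundary
tolerance V (default 10 bp): every defining endpoint may deviate by at
most V from the cataloged event.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

from .events import ASEvent, EventCatalog, EventType
from .model import GenomicInterval, Transcript, TranscriptSet

__all__ = [
    "EventQuant",
    "transcript_harbors_form",
    "quantify_event",
    "quantify_catalog",
]


@dataclass
class EventQuant:
    """Quantification of one event in one sample.

    ``fpkm_on``/``fpkm_off`` are None when no transcript harbors that form
    in the sample. ``R`` is None when total event expression is zero.
    """

    event_id: str
    sample_id: str
    fpkm_on: float | None
    fpkm_off: float | None

    @property
    def R(self) -> float | None:
        on = self.fpkm_on or 0.0
        off = self.fpkm_off or 0.0
        total = on + off
        if total <= 0:
            return None
        return on / total

    @property
    def presence(self) -> str:
        on = (self.fpkm_on or 0.0) > 0
        off = (self.fpkm_off or 0.0) > 0
        if on and off:
            return "both"
        if on:
            return "on_only"
        if off:
            return "off_only"
        return "absent"


def _close(x: int, y: int, V: int) -> bool:
    return abs(x - y) <= V


def _has_exon_like(t: Transcript, iv: GenomicInterval, V: int) -> bool:
    return any(
        _close(e.start, iv.start, V) and _close(e.end, iv.end, V) for e in t.exons
    )


def _has_intron_like(t: Transcript, iv: GenomicInterval, V: int) -> bool:
    return any(
        _close(i.start, iv.start, V) and _close(i.end, iv.end, V)
        for i in t.introns()
    )


def _alt_variants(e: ASEvent) -> tuple[GenomicInterval, GenomicInterval]:
    """(on_variant, off_variant) exon for the ALT event types; the 'on'
    role goes to the longer variant, ties to the smaller start."""
    va, vb = e.target_exons
    if (va.length, -va.start) > (vb.length, -vb.start):
        return va, vb
    return vb, va


def _matches_form(t: Transcript, e: ASEvent, form: str, V: int) -> bool:
    if e.event_type in (EventType.SKIP, EventType.CASSETTE):
        if form == "on":
            return (
                all(_has_exon_like(t, x, V) for x in e.target_exons)
                and _has_intron_like(t, e.flank_intron_left, V)
                and _has_intron_like(t, e.flank_intron_right, V)
            )
        return _has_intron_like(t, e.spanning_intron, V)
    if e.event_type in (EventType.IR_single, EventType.IR_multi):
        if form == "on":
            return _has_exon_like(t, e.retention_exon, V)
        return all(_has_intron_like(t, x, V) for x in e.target_exons)
    on_var, off_var = _alt_variants(e)
    return _has_exon_like(t, on_var if form == "on" else off_var, V)


def transcript_harbors_form(
    t: Transcript, e: ASEvent, form: str, V: int = 10
) -> bool:
    """Does transcript ``t`` carry the 'on' or the 'off' form of event ``e``?

    All defining boundaries of the form must be present in ``t`` within V
    base pairs. A transcript that would satisfy both forms at once (possible
    only for degenerate V, at least half the smallest intron involved) is
    assigned to neither, with a warning.
    """
    if form not in ("on", "off"):
        raise ValueError("form must be 'on' or 'off'")
    if V < 0:
        raise ValueError("tolerance V must be >= 0")
    if t.chrom != e.chrom:
        return False
    this = _matches_form(t, e, form, V)
    if not this:
        return False
    other = _matches_form(t, e, "off" if form == "on" else "on", V)
    if other:
        warnings.warn(
            f"transcript {t.transcript_id} matches both forms of "
            f"{e.event_id} at V={V}; assigned to neither",
            stacklevel=2,
        )
        return False
    return True


def quantify_event(e: ASEvent, ts: TranscriptSet, V: int = 10) -> EventQuant:
    """FPKM_on, FPKM_off and R for one event in one sample.

    Sums FPKM over all transcripts of the event's gene harboring each form.
    Transcripts without an FPKM value contribute 0, with a warning.
    """
    on_sum: float | None = None
    off_sum: float | None = None
    for t in ts:
        if t.gene_id != e.gene_id:
            continue
        for form in ("on", "off"):
            if transcript_harbors_form(t, e, form, V):
                fpkm = t.fpkm
                if fpkm is None:
                    warnings.warn(
                        f"transcript {t.transcript_id} has no FPKM; "
                        "treated as 0",
                        stacklevel=2,
                    )
                    fpkm = 0.0
                if form == "on":
                    on_sum = (on_sum or 0.0) + fpkm
                else:
                    off_sum = (off_sum or 0.0) + fpkm
    return EventQuant(
        event_id=e.event_id, sample_id=ts.sample_id, fpkm_on=on_sum, fpkm_off=off_sum
    )


def quantify_catalog(
    catalog: EventCatalog,
    samples: Iterable[TranscriptSet],
    V: int = 10,
) -> dict[tuple[str, str], EventQuant]:
    """Quantify every catalog event in every sample.

    Returns a mapping ``(event_id, sample_id) -> EventQuant``. Transcripts
    are pre-grouped by gene so the cost is linear in catalog size times the
    isoform count of each event's gene.
    """
    out: dict[tuple[str, str], EventQuant] = {}
    for ts in samples:
        by_gene = ts.by_gene()
        for e in catalog:
            gene_ts = TranscriptSet(sample_id=ts.sample_id)
            for t in by_gene.get(e.gene_id, []):
                gene_ts.add(t)
            out[(e.event_id, ts.sample_id)] = quantify_event(e, gene_ts, V)
    return out
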