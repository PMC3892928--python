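"""Tabular output: TSV serialisation of catalogs, quantifications and
comparisons, plus the percentage arithmetic used in summaries."""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd

from .events import ASEvent, EventCatalog, RedundancyReport
from .novelty import NoveltyLabel
from .profiles import ComparisonMatrix, ProfileComparison
from .quantify import EventQuant

__all__ = [
    "percent",
    "catalog_table",
    "read_catalog_table",
    "quant_table",
    "comparison_table",
    "pair_summary_table",
    "novelty_table",
    "redundancy_summary",
]


def percent(part: float, whole: float, ndigits: int = 1) -> float:
    """``part`` as a percentage of ``whole``, rounded to ``ndigits``."""
    if whole == 0:
        raise ZeroDivisionError("percentage of an empty total")
    return round(100.0 * part / whole, ndigits)


def _coords(ivs: Iterable) -> str:
    return ",".join(f"{iv.start}-{iv.end}" for iv in ivs)


def catalog_table(catalog: EventCatalog) -> pd.DataFrame:
    """One row per event: identity, coordinates and supporter counts."""
    rows = []
    for ev in catalog:
        rows.append(
            {
                "event_id": ev.event_id,
                "event_type": ev.event_type.value,
                "gene_id": ev.gene_id,
                "chrom": ev.chrom,
                "strand": ev.strand,
                "target_exons": _coords(ev.target_exons),
                "flank_intron_left": _coords(
                    [ev.flank_intron_left] if ev.flank_intron_left else []
                ),
                "flank_intron_right": _coords(
                    [ev.flank_intron_right] if ev.flank_intron_right else []
                ),
                "spanning_intron": _coords(
                    [ev.spanning_intron] if ev.spanning_intron else []
                ),
                "retention_exon": _coords(
                    [ev.retention_exon] if ev.retention_exon else []
                ),
                "n_on": ev.n_on,
                "n_off": ev.n_off,
                "within_sample": ev.within_sample,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "event_id",
            "event_type",
            "gene_id",
            "chrom",
            "strand",
            "target_exons",
            "flank_intron_left",
            "flank_intron_right",
            "spanning_intron",
            "retention_exon",
            "n_on",
            "n_off",
            "within_sample",
        ],
    ).sort_values("event_id").reset_index(drop=True)


def read_catalog_table(source) -> EventCatalog:
    """Rebuild an :class:`EventCatalog` from a catalog TSV (or DataFrame).

    Supporter sets are not serialised, so the rebuilt events carry empty
    supporter sets (the ``n_on``/``n_off`` columns remain in the file for
    inspection); coordinates and event ids round-trip exactly.
    """
    from .events import EventType
    from .model import GenomicInterval

    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)

    def _parse(chrom: str, strand: str, text: str) -> list:
        if not text:
            return []
        out = []
        for part in text.split(","):
            s, e = part.split("-")
            out.append(GenomicInterval(chrom, int(s), int(e), strand))
        return out

    catalog = EventCatalog()
    for _, row in df.iterrows():
        chrom, strand = row["chrom"], row["strand"]
        flank_l = _parse(chrom, strand, row["flank_intron_left"])
        flank_r = _parse(chrom, strand, row["flank_intron_right"])
        span = _parse(chrom, strand, row["spanning_intron"])
        ret = _parse(chrom, strand, row.get("retention_exon", ""))
        catalog.add(
            ASEvent(
                event_type=EventType(row["event_type"]),
                chrom=chrom,
                strand=strand,
                gene_id=row["gene_id"],
                target_exons=tuple(_parse(chrom, strand, row["target_exons"])),
                flank_intron_left=flank_l[0] if flank_l else None,
                flank_intron_right=flank_r[0] if flank_r else None,
                spanning_intron=span[0] if span else None,
                retention_exon=ret[0] if ret else None,
            )
        )
    return catalog


def _fmt_ratio(r: float | None) -> str:
    return "" if r is None else f"{r:.6f}"


def quant_table(quants: Mapping[tuple[str, str], EventQuant]) -> pd.DataFrame:
    """One row per (event, sample); R with 6 decimals, empty when undefined."""
    rows = []
    for (eid, sid) in sorted(quants):
        q = quants[(eid, sid)]
        rows.append(
            {
                "event_id": eid,
                "sample_id": sid,
                "fpkm_on": "" if q.fpkm_on is None else f"{q.fpkm_on:.6f}",
                "fpkm_off": "" if q.fpkm_off is None else f"{q.fpkm_off:.6f}",
                "R": _fmt_ratio(q.R),
                "presence": q.presence,
            }
        )
    return pd.DataFrame(
        rows, columns=["event_id", "sample_id", "fpkm_on", "fpkm_off", "R", "presence"]
    )


def comparison_table(comparisons: Sequence[ProfileComparison]) -> pd.DataFrame:
    rows = [
        {
            "event_id": c.event_id,
            "sample_i": c.sample_i,
            "sample_j": c.sample_j,
            "Ri": _fmt_ratio(c.r_i),
            "Rj": _fmt_ratio(c.r_j),
            "delta": _fmt_ratio(c.delta),
            "class": c.klass,
        }
        for c in comparisons
    ]
    return pd.DataFrame(
        rows,
        columns=["event_id", "sample_i", "sample_j", "Ri", "Rj", "delta", "class"],
    )


def pair_summary_table(matrix: ComparisonMatrix) -> pd.DataFrame:
    return matrix.to_dataframe()


def novelty_table(
    catalog: EventCatalog,
    labels: Mapping[str, NoveltyLabel],
    per_source: Mapping[str, Mapping[str, bool]] | None = None,
) -> pd.DataFrame:
    """Event novelty labels, optionally with per-annotation-source flags."""
    rows = []
    for ev in catalog:
        lab = labels[ev.event_id]
        row = {
            "event_id": ev.event_id,
            "event_type": ev.event_type.value,
            "exon_status": lab.exon_status,
            "intron_status": lab.intron_status,
            "event_status": lab.event_status,
        }
        if per_source is not None:
            for src, known in per_source[ev.event_id].items():
                row[f"known_in_{src}"] = known
        rows.append(row)
    return pd.DataFrame(rows).sort_values("event_id").reset_index(drop=True)


def redundancy_summary(report: RedundancyReport, ndigits: int = 2) -> dict:
    """Counts and the redundant percentage at the requested precision."""
    return {
        "wobble": report.wobble,
        "n_events": report.n_events,
        "n_clusters": report.n_clusters,
        "n_redundant": report.n_redundant,
        "redundant_percent": (
            percent(report.n_redundant, report.n_events, ndigits)
            if report.n_events
            else 0.0
        ),
    }
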