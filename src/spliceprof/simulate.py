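"""Synthetic multi-sample transcriptomes with planted splicing events.

The generator emulates a multi-tissue assembly experiment: each gene is a
backbone exon chain plus one alternate isoform per planted event (exon
skipping, cassette exons, intron retention, alternative starts/ends,
alternative exon ends). Isoform FPKM profiles across samples follow a
log-normal expression model; for cohorts with one event per gene a planted
class mix dictates the pairwise splicing relation (stable / variable /
switch / absent) between the first two samples. A configurable fraction of
events is made novel by withholding the event's alternate isoform from the
emitted annotation. Everything is keyed to a single integer seed and the
generator records a complete truth table: expected event coordinates and
supporters, per-sample FPKM_on/FPKM_off, expected novelty labels and the
expected pairwise class.

Planted events within a gene are spaced at least one backbone exon apart
and kept away from the terminal exons, so that pairwise comparison of any
two isoforms yields exactly the planted events and nothing else.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable

import pandas as pd
import yaml

from .events import ASEvent, EventType
from .model import GenomicInterval, Transcript, TranscriptSet, write_gtf

__all__ = ["ConfigError", "SimConfig", "PlantedEvent", "TruthTable", "SimResult", "generate"]

# 16 human tissues of a body-map style cohort
DEFAULT_SAMPLES = [
    "adipose", "adrenal", "brain", "breast", "colon", "heart", "kidney",
    "liver", "lung", "lymph_node", "ovary", "prostate", "skeletal_muscle",
    "testes", "thyroid", "white_blood_cells",
]

# backbone exons consumed by each anchored event type
_ANCHOR_WIDTH = {
    "SKIP": 1,
    "CASSETTE": 2,
    "IR_single": 2,
    "IR_multi": 3,
    "ALT_EXON_ENDS": 1,
}
_TERMINAL_TYPES = ("ALT_START", "ALT_END")
_ALL_TYPES = tuple(_ANCHOR_WIDTH) + _TERMINAL_TYPES


class ConfigError(ValueError):
    """The simulation configuration is inconsistent or infeasible."""


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults model a 16-tissue cohort with mostly-included skipped exons
    (``on_bias``), low-to-medium log-normal expression, a novel-event
    majority, and pairwise class proportions of roughly 30% stable, 10%
    variable, 5% switch with the remainder absent from one or both
    samples.
    """

    n_genes: int = 100
    samples: list[str] = field(default_factory=lambda: list(DEFAULT_SAMPLES))
    exons_per_gene: tuple[int, int] = (8, 12)
    exon_len: tuple[int, int] = (100, 300)
    intron_len: tuple[int, int] = (200, 2000)
    events_per_gene: dict[str, int] = field(
        default_factory=lambda: {"SKIP": 1, "IR_single": 1}
    )
    fpkm_mu: float = 1.0       # log-normal location of isoform FPKM
    fpkm_sigma: float = 1.0    # log-normal scale
    on_bias: float = 0.75      # P(exon-containing form is the major form)
    class_mix: dict[str, float] = field(
        default_factory=lambda: {
            "stable": 0.30,
            "variable": 0.10,
            "switch": 0.05,
            "absent": 0.55,
        }
    )
    present_rate: float = 0.7  # per-sample isoform presence (multi-event genes)
    novel_fraction: float = 0.6
    annotation_jitter: int = 0  # <=W boundary jitter of the annotation
    tolerance_v: int = 10       # quantification tolerance the cohort must respect
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("exons_per_gene", "exon_len", "intron_len"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ConfigError(f"bad range {name}={lo, hi}")
            setattr(self, name, (int(lo), int(hi)))
        if self.n_genes < 0:
            raise ConfigError("n_genes must be >= 0")
        if not self.samples or len(set(self.samples)) != len(self.samples):
            raise ConfigError("samples must be non-empty and unique")
        for t, k in self.events_per_gene.items():
            if t not in _ALL_TYPES:
                raise ConfigError(f"unknown event type {t!r}")
            if k < 0:
                raise ConfigError(f"negative count for {t}")
        for t in _TERMINAL_TYPES:
            if self.events_per_gene.get(t, 0) > 1:
                raise ConfigError(f"at most one {t} event per gene")
        total = sum(self.class_mix.get(c, 0.0) for c in ("stable", "variable", "switch", "absent"))
        if abs(total - 1.0) > 1e-9 or any(v < 0 for v in self.class_mix.values()):
            raise ConfigError("class_mix must be non-negative and sum to 1")
        if not (0 <= self.on_bias <= 1 and 0 < self.present_rate <= 1):
            raise ConfigError("on_bias in [0,1], present_rate in (0,1] required")
        if not (0 <= self.novel_fraction <= 1):
            raise ConfigError("novel_fraction must be in [0,1]")
        if self.annotation_jitter < 0 or self.tolerance_v < 0:
            raise ConfigError("tolerances must be >= 0")
        # boundary tolerances must not be able to bridge a whole intron,
        # and terminal/exon-end shifts must exceed 2V to stay unambiguous
        shift_max = 2 * self.tolerance_v + 20
        if self.intron_len[0] <= 2 * self.tolerance_v:
            raise ConfigError(
                f"minimum intron length {self.intron_len[0]} must exceed "
                f"2*V = {2 * self.tolerance_v}"
            )
        if self.exon_len[0] <= shift_max + 1:
            raise ConfigError(
                f"minimum exon length {self.exon_len[0]} too small for "
                f"boundary shifts up to {shift_max}"
            )
        if self.intron_len[0] <= 2 * self.annotation_jitter + 1:
            raise ConfigError("introns too short for the annotation jitter")

    @classmethod
    def from_yaml(cls, source: str | IO[str]) -> "SimConfig":
        if isinstance(source, str) and "\n" not in source and ":" not in source:
            with open(source) as fh:
                data = yaml.safe_load(fh)
        else:
            data = yaml.safe_load(source)  # type: ignore[arg-type]
        data = data or {}
        for key in ("exons_per_gene", "exon_len", "intron_len"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass
class PlantedEvent:
    """Ground truth for one planted event."""

    event: ASEvent  # expected coordinates and supporter sets
    novel: bool
    exon_status: str
    intron_status: str
    expected_class: str | None  # pairwise class for the first two samples
    quants: dict[str, tuple[float | None, float | None]]  # sample -> (on, off)

    @property
    def event_id(self) -> str:
        return self.event.event_id

    @property
    def event_type(self) -> EventType:
        return self.event.event_type

    def expected_R(self, sample: str) -> float | None:
        on, off = self.quants.get(sample, (None, None))
        total = (on or 0.0) + (off or 0.0)
        if total <= 0:
            return None
        return (on or 0.0) / total

    @property
    def discoverable(self) -> bool:
        """Both forms emitted somewhere in the cohort, so pooled extraction
        must find the event."""
        return bool(self.event.on_transcripts) and bool(self.event.off_transcripts)


@dataclass
class TruthTable:
    samples: list[str]
    events: list[PlantedEvent] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def event_ids(self) -> set[str]:
        return {p.event_id for p in self.events}

    def discoverable_ids(self, types: Iterable[EventType] | None = None) -> set[str]:
        wanted = set(types) if types is not None else None
        return {
            p.event_id
            for p in self.events
            if p.discoverable and (wanted is None or p.event_type in wanted)
        }

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for p in self.events:
            row = {
                "event_id": p.event_id,
                "event_type": p.event_type.value,
                "gene_id": p.event.gene_id,
                "chrom": p.event.chrom,
                "strand": p.event.strand,
                "novel": p.novel,
                "exon_status": p.exon_status,
                "intron_status": p.intron_status,
                "expected_class": p.expected_class or "",
            }
            for s in self.samples:
                on, off = p.quants.get(s, (None, None))
                row[f"fpkm_on:{s}"] = "" if on is None else f"{on:.6f}"
                row[f"fpkm_off:{s}"] = "" if off is None else f"{off:.6f}"
            rows.append(row)
        return pd.DataFrame(rows)

    def write_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


@dataclass
class SimResult:
    config: SimConfig
    sample_sets: dict[str, TranscriptSet]
    annotation: TranscriptSet
    truth: TruthTable

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sample in self.config.samples:
            write_gtf(self.sample_sets[sample], str(outdir / f"{sample}.gtf"))
        write_gtf(self.annotation, str(outdir / "annotation.gtf"))
        self.truth.write_tsv(outdir / "truth.tsv")


# ---------------------------------------------------------------------------
# gene construction


@dataclass
class _GenePlan:
    gene_id: str
    chrom: str
    strand: str
    isoforms: list[list[GenomicInterval]]  # index 0 = backbone
    # per planted event: (type label, expected ASEvent skeleton,
    #                     on/off quantification-carrier iso indices,
    #                     on/off catalog-supporter iso indices, novel flag)
    events: list[tuple[str, ASEvent, set[int], set[int], set[int], set[int], bool]]


def _iv(chrom: str, start: int, end: int, strand: str) -> GenomicInterval:
    return GenomicInterval(chrom, start, end, strand)


def _build_gene(
    rng: random.Random, cfg: SimConfig, gene_idx: int, cursors: dict[str, int]
) -> _GenePlan:
    gene_id = f"G{gene_idx:05d}"
    chrom = f"chr{gene_idx % 4 + 1}"
    strand = rng.choice("+-")
    V = cfg.tolerance_v

    anchored = [t for t in _ANCHOR_WIDTH for _ in range(cfg.events_per_gene.get(t, 0))]
    terminal = [t for t in _TERMINAL_TYPES if cfg.events_per_gene.get(t, 0)]
    rng.shuffle(anchored)

    # assign non-adjacent anchor blocks on internal exons, away from both ends
    anchors: list[tuple[str, int]] = []
    pos = 2
    for t in anchored:
        pos += rng.randint(0, 1)
        anchors.append((t, pos))
        pos += _ANCHOR_WIDTH[t] + 1
    min_exons = max(pos - 1 + 3, 4)
    n_exons = max(rng.randint(*cfg.exons_per_gene), min_exons)

    reserve = cfg.intron_len[1] + cfg.exon_len[1] + 200
    start = cursors.get(chrom, 1_000_000) + reserve
    exons: list[GenomicInterval] = []
    cur = start
    for i in range(n_exons):
        ln = rng.randint(*cfg.exon_len)
        exons.append(_iv(chrom, cur, cur + ln - 1, strand))
        cur = cur + ln + rng.randint(*cfg.intron_len)
    cursors[chrom] = exons[-1].end + reserve

    def intron(i: int) -> GenomicInterval:
        return _iv(chrom, exons[i].end + 1, exons[i + 1].start - 1, strand)

    isoforms: list[list[GenomicInterval]] = [list(exons)]
    # per event: (type label, expected skeleton, alt isoform index,
    #             whether the alternate isoform carries the 'on' form, novel)
    raw_events: list[tuple[str, ASEvent, int, bool, bool]] = []

    def shift() -> int:
        return rng.randint(2 * V + 5, 2 * V + 20)

    def add_event(
        t: str, alt: list[GenomicInterval], ev: ASEvent, alt_is_on: bool
    ) -> None:
        isoforms.append(alt)
        raw_events.append(
            (t, ev, len(isoforms) - 1, alt_is_on, rng.random() < cfg.novel_fraction)
        )

    for t, k in anchors:
        if t == "SKIP":
            alt = exons[:k] + exons[k + 1 :]
            ev = ASEvent(
                event_type=EventType.SKIP,
                chrom=chrom,
                strand=strand,
                gene_id=gene_id,
                target_exons=(exons[k],),
                flank_intron_left=intron(k - 1),
                flank_intron_right=intron(k),
                spanning_intron=_iv(chrom, intron(k - 1).start, intron(k).end, strand),
            )
            add_event(t, alt, ev, alt_is_on=False)
        elif t == "CASSETTE":
            alt = exons[:k] + exons[k + 2 :]
            ev = ASEvent(
                event_type=EventType.CASSETTE,
                chrom=chrom,
                strand=strand,
                gene_id=gene_id,
                target_exons=(exons[k], exons[k + 1]),
                flank_intron_left=intron(k - 1),
                flank_intron_right=intron(k + 1),
                spanning_intron=_iv(
                    chrom, intron(k - 1).start, intron(k + 1).end, strand
                ),
            )
            add_event(t, alt, ev, alt_is_on=False)
        elif t in ("IR_single", "IR_multi"):
            span = 1 if t == "IR_single" else 2
            merged = _iv(chrom, exons[k].start, exons[k + span].end, strand)
            alt = exons[:k] + [merged] + exons[k + span + 1 :]
            ev = ASEvent(
                event_type=EventType[t],
                chrom=chrom,
                strand=strand,
                gene_id=gene_id,
                target_exons=tuple(intron(k + j) for j in range(span)),
                retention_exon=merged,
            )
            add_event(t, alt, ev, alt_is_on=True)
        else:  # ALT_EXON_ENDS: shrink the 3'-boundary-side of an internal exon
            short = _iv(chrom, exons[k].start, exons[k].end - shift(), strand)
            alt = exons[:k] + [short] + exons[k + 1 :]
            ev = ASEvent(
                event_type=EventType.ALT_EXON_ENDS,
                chrom=chrom,
                strand=strand,
                gene_id=gene_id,
                target_exons=tuple(sorted([short, exons[k]])),
            )
            add_event(t, alt, ev, alt_is_on=False)  # original (longer) is 'on'

    for t in terminal:
        genomic_left = (t == "ALT_START") == (strand != "-")
        if t == "ALT_START":
            # a different, non-overlapping terminal exon at the 5' end
            ln = rng.randint(*cfg.exon_len)
            gap = rng.randint(*cfg.intron_len)
            if genomic_left:
                u = _iv(chrom, exons[0].start - gap - ln, exons[0].start - gap - 1, strand)
                alt = [u] + exons[1:]
                variants = tuple(sorted([u, exons[0]]))
            else:
                u = _iv(chrom, exons[-1].end + gap, exons[-1].end + gap + ln - 1, strand)
                alt = exons[:-1] + [u]
                variants = tuple(sorted([u, exons[-1]]))
            ev = ASEvent(
                event_type=EventType.ALT_START,
                chrom=chrom,
                strand=strand,
                gene_id=gene_id,
                target_exons=variants,
            )
            va, vb = variants
            alt_var = u
            other = variants[0] if variants[1] == u else variants[1]
            alt_is_on = (alt_var.length, -alt_var.start) > (other.length, -other.start)
            add_event(t, alt, ev, alt_is_on=alt_is_on)
        else:  # ALT_END: extend the 3'-terminal exon outward
            s = shift()
            if genomic_left:
                ext = _iv(chrom, exons[0].start - s, exons[0].end, strand)
                alt = [ext] + exons[1:]
                variants = tuple(sorted([ext, exons[0]]))
            else:
                ext = _iv(chrom, exons[-1].start, exons[-1].end + s, strand)
                alt = exons[:-1] + [ext]
                variants = tuple(sorted([ext, exons[-1]]))
            ev = ASEvent(
                event_type=EventType.ALT_END,
                chrom=chrom,
                strand=strand,
                gene_id=gene_id,
                target_exons=variants,
            )
            add_event(t, alt, ev, alt_is_on=True)  # extended variant is longer

    # events are spaced apart, so every isoform other than an event's own
    # alternate carries that event's shared (backbone-side) form; those are
    # the quantification carriers. Catalog supporters differ for the
    # chain-sensitive ALT types: only the (backbone, alternate) pair has the
    # otherwise-identical intron chains the comparison requires, so only
    # those two isoforms can appear as supporters.
    n_iso = len(isoforms)
    events = []
    for t, ev, alt_idx, alt_is_on, novel in raw_events:
        rest = set(range(n_iso)) - {alt_idx}
        on_set, off_set = ({alt_idx}, rest) if alt_is_on else (rest, {alt_idx})
        if t in ("ALT_START", "ALT_END", "ALT_EXON_ENDS"):
            sup_on, sup_off = (
                ({alt_idx}, {0}) if alt_is_on else ({0}, {alt_idx})
            )
        else:
            sup_on, sup_off = on_set, off_set
        events.append((t, ev, on_set, off_set, sup_on, sup_off, novel))
    return _GenePlan(gene_id, chrom, strand, isoforms, events)


# ---------------------------------------------------------------------------
# expression planning


def _bias_draw(rng: random.Random, on_bias: float) -> float:
    if rng.random() < on_bias:
        return rng.uniform(0.5, 1.0)
    return rng.uniform(0.0, 0.5)


def _draw_total(rng: random.Random, cfg: SimConfig) -> float:
    return max(rng.lognormvariate(cfg.fpkm_mu, cfg.fpkm_sigma), 0.2)


def _plan_pair_classes(
    rng: random.Random, cfg: SimConfig
) -> tuple[str, float | None, float | None]:
    """Draw a class from the mix and inclusion ratios realising it for the
    first two samples. None means the event is absent from that sample.
    Target deltas keep a margin from the class boundaries so that FPKM
    rounding at 6 decimals cannot move an event across a boundary."""
    classes = ("stable", "variable", "switch", "absent")
    weights = [cfg.class_mix.get(c, 0.0) for c in classes]
    c = rng.choices(classes, weights=weights)[0]
    if c == "absent":
        u = rng.random()
        if u < 1 / 3:
            return c, None, _bias_draw(rng, cfg.on_bias)
        if u < 2 / 3:
            return c, _bias_draw(rng, cfg.on_bias), None
        return c, None, None
    if c == "stable":
        r = _bias_draw(rng, cfg.on_bias)
        return c, r, r
    lo_d, hi_d = (0.12, 0.48) if c == "variable" else (0.52, 0.92)
    delta = rng.uniform(lo_d, hi_d)
    lo = rng.uniform(0.0, 1.0 - delta)
    hi = lo + delta
    return (c, hi, lo) if rng.random() < 0.5 else (c, lo, hi)


# ---------------------------------------------------------------------------
# novelty planning


def _expected_novelty(etype: str, novel: bool) -> tuple[str, str]:
    if not novel:
        return "known", "known"
    if etype in ("SKIP", "CASSETTE"):
        return "known", "novel"  # the spanning intron is withheld
    if etype in ("IR_single", "IR_multi"):
        return "novel_overlapping", "known"  # the retention exon is withheld
    if etype == "ALT_START":
        return "novel_nonoverlapping", "known"  # disjoint new terminal exon
    return "novel_overlapping", "known"  # ALT_END / ALT_EXON_ENDS variants


def _jitter_isoform(
    rng: random.Random, exons: list[GenomicInterval], j: int
) -> list[GenomicInterval]:
    if j == 0:
        return exons
    out = []
    for e in exons:
        out.append(
            GenomicInterval(
                e.chrom,
                e.start + rng.randint(-j, j),
                e.end + rng.randint(-j, j),
                e.strand,
            )
        )
    return out


# ---------------------------------------------------------------------------


def generate(cfg: SimConfig) -> SimResult:
    """Generate the cohort: per-sample transcript sets, an annotation, and
    the truth table. Deterministic for a fixed config and seed."""
    rng = random.Random(cfg.seed)
    cursors: dict[str, int] = {}
    sample_sets = {s: TranscriptSet(sample_id=s) for s in cfg.samples}
    annotation = TranscriptSet(sample_id="annotation")
    truth = TruthTable(samples=list(cfg.samples))
    s0 = cfg.samples[0]
    s1 = cfg.samples[1] if len(cfg.samples) > 1 else None

    for g in range(cfg.n_genes):
        plan = _build_gene(rng, cfg, g, cursors)
        n_iso = len(plan.isoforms)
        tids = [f"{plan.gene_id}.{i + 1}" for i in range(n_iso)]

        # per-sample isoform FPKM (None = isoform absent in that sample)
        fpkm: dict[str, list[float | None]] = {s: [None] * n_iso for s in cfg.samples}
        expected_class: str | None = None
        single_event = len(plan.events) == 1 and n_iso == 2

        if single_event and s1 is not None:
            _, ev, on_set, off_set, _, _, _ = plan.events[0]
            on_idx, off_idx = next(iter(on_set)), next(iter(off_set))
            expected_class, r0, r1 = _plan_pair_classes(rng, cfg)
            for s, r in ((s0, r0), (s1, r1)):
                if r is None:
                    continue
                total = _draw_total(rng, cfg)
                on_val = round(r * total, 6)
                off_val = round((1.0 - r) * total, 6)
                if on_val > 0:
                    fpkm[s][on_idx] = on_val
                if off_val > 0:
                    fpkm[s][off_idx] = off_val
            for s in cfg.samples[2:]:
                if rng.random() < cfg.present_rate:
                    r = _bias_draw(rng, cfg.on_bias)
                    total = _draw_total(rng, cfg)
                    on_val = round(r * total, 6)
                    off_val = round((1.0 - r) * total, 6)
                    if on_val > 0:
                        fpkm[s][on_idx] = on_val
                    if off_val > 0:
                        fpkm[s][off_idx] = off_val
        else:
            for s in cfg.samples:
                for i in range(n_iso):
                    if rng.random() < cfg.present_rate:
                        fpkm[s][i] = round(
                            max(rng.lognormvariate(cfg.fpkm_mu, cfg.fpkm_sigma), 0.05),
                            6,
                        )

        for s in cfg.samples:
            for i in range(n_iso):
                if fpkm[s][i] is None:
                    continue
                sample_sets[s].add(
                    Transcript(
                        transcript_id=tids[i],
                        gene_id=plan.gene_id,
                        sample_id=s,
                        exons=list(plan.isoforms[i]),
                        fpkm=fpkm[s][i],
                    )
                )

        # annotation: backbone always; each alternate isoform unless its
        # event was drawn novel
        ann_iso = [0] + [
            i + 1
            for i, (_, _, _, _, _, _, novel) in enumerate(plan.events)
            if not novel
        ]
        for i in ann_iso:
            annotation.add(
                Transcript(
                    transcript_id=f"{tids[i]}.ann",
                    gene_id=plan.gene_id,
                    sample_id="annotation",
                    exons=_jitter_isoform(rng, plan.isoforms[i], cfg.annotation_jitter),
                )
            )

        # truth records: supporters and structural per-sample quantification
        for etype, ev, on_set, off_set, sup_on, sup_off, novel in plan.events:
            quants: dict[str, tuple[float | None, float | None]] = {}
            for s in cfg.samples:
                on_sum: float | None = None
                off_sum: float | None = None
                for i in range(n_iso):
                    val = fpkm[s][i]
                    if val is None:
                        continue
                    if i in on_set:
                        on_sum = (on_sum or 0.0) + val
                    elif i in off_set:
                        off_sum = (off_sum or 0.0) + val
                    if i in sup_on:
                        ev.on_transcripts.add((s, tids[i]))
                    elif i in sup_off:
                        ev.off_transcripts.add((s, tids[i]))
                quants[s] = (on_sum, off_sum)
            exon_status, intron_status = _expected_novelty(etype, novel)
            truth.events.append(
                PlantedEvent(
                    event=ev,
                    novel=novel,
                    exon_status=exon_status,
                    intron_status=intron_status,
                    expected_class=expected_class if single_event else None,
                    quants=quants,
                )
            )

    return SimResult(
        config=cfg, sample_sets=sample_sets, annotation=annotation, truth=truth
    )
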