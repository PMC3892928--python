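# Methods

## Scope and data model

`spliceprof` consumes assembled transcript models, not reads: one GTF per
sample (or a concatenated multi-sample GTF whose gene identifiers were
reconciled beforehand, e.g. with Cuffcompare), in which only `exon`
feature lines are used and isoform expression arrives as an `FPKM`
attribute. Alignment, assembly and FPKM estimation are out of scope, as
are read-level evidence (junction counts) and any significance testing —
with one sample per condition the cross-sample comparisons are
qualitative by design.

Coordinates are 1-based and inclusive at both ends (the GTF convention),
so an exon written `101 200` is 100 bp long. A transcript is an ordered
chain of non-overlapping exons on one chromosome and strand; introns are
the inter-exon gaps, derived on demand and never stored. A missing FPKM
attribute is kept as "absent", distinct from 0. Single-exon transcripts
are retained and flagged; event discovery considers only multi-exon
structures (the intron chain is the comparison currency), except that the
intron-retaining form of a retention event may be single-exon. Chromosome
names are compared as exact strings; an optional alias map applied at
parse time handles `chr`-prefix mismatches. Transcripts with unknown
strand (unstranded libraries) participate normally; an event's strand is
inherited from its transcripts and recorded unknown when they disagree.

## Event definitions

All unordered transcript pairs within a gene are compared (n isoforms
yield n(n−1)/2 comparisons); genes whose summed transcript FPKM fails to
reach 0.1 in every sample are excluded (genes entirely without FPKM are
kept). Event classes, from one pair (a, b):

* **SKIP** — b has consecutive introns (i_left, i_right) flanking exactly
  one exon, and a has a single intron spanning (i_left.start,
  i_right.end). Flanking boundaries must match the spanning intron
  exactly. b is the *on* form, a the *off* form.
* **CASSETTE** — as SKIP with two or more exons inside the spanning
  intron. The one-vs-several split keeps SKIP aligned with the
  single-exon definition above; joint skipping of k ≥ 2 exons is one
  cassette event, not k skip events.
* **IR_single / IR_multi** — one exon of the retaining (*on*) form covers
  an exon–intron–…–exon span of the spliced (*off*) form with both outer
  boundaries shared; one retained intron is single, several consecutive
  ones multi.
* **ALT_START / ALT_END** — the terminal exon differs at its outer
  boundary while the intron chain is otherwise identical (the terminal
  exon may also be replaced entirely, i.e. its inner boundary moves with
  the first/last intron's outer end). Labels follow transcription
  direction: on the minus strand the genomic-left variation is the
  transcript end. Unknown-strand events default to genomic left = start.
* **ALT_EXON_ENDS** — one *internal* exon shares one boundary and differs
  at the other, with the intron chains otherwise identical. The stricter
  internal-only reading is deliberate: a terminal exon whose inner
  boundary alone differs is not classified (noted for curation rather
  than guessed at).

For the terminal/exon-end classes the on/off roles are not dictated by
the definition; the longer variant exon is assigned *on* (ties to the
smaller start) so that role assignment is deterministic and symmetric in
argument order.

Events are identified by type, chromosome, strand and defining
coordinates; identical events found in different pairs merge into one
catalog entry whose supporter sets accumulate, and the catalog records
whether both forms co-occur within a single sample. Event identity is
exact-coordinate on purpose. Near-redundancy — co-located same-type
events whose corresponding boundaries each differ by at most a wobble
(default 5 bp, the scale of spliced-alignment imprecision) — is reported
separately: single-linkage transitive closure over the pairwise
within-wobble relation, keeping per cluster the event with the most
supporting transcripts (ties to smallest coordinates). Closure makes the
collapse idempotent. The clustering rule and representative choice are
this package's design decisions; only the tolerance itself is canonical.

## Novelty classification

Reference annotations are plain transcript GTFs; exons are indexed
directly and introns derived from each annotated transcript's chain
(interval trees per chromosome and kind). Spliced-alignment evidence
(e.g. EST alignments in BED12) is ingested the same way — blocks as
exons, block gaps as introns — and treated as just another source. A
query feature matches an annotated feature of the same kind when both
endpoint deviations are ≤ W (default 5 bp; the same W applies to exons
and introns); among candidates the minimal total deviation wins. A
feature is *known* if matched in **any** source, so adding sources can
only shrink the novel set, and the known set grows monotonically in W.

An event's exon features (target exons, or the retention exon for IR)
and intron features (flanking and spanning introns, or the retained
introns for IR) are classified separately; the event is known only if
all are. A novel exon still overlapping some annotated exon by ≥ 1 bp
(strand-agnostic when either strand is unknown) is `novel_overlapping` —
only its boundaries are new — against `novel_nonoverlapping` for exons
in unannotated territory. Occurrence binning counts, per distinct
feature, the samples contributing a supporting transcript for the form
that carries it (the *on* form for exons and flanking introns, the *off*
form for spanning/retained introns).

## Quantification

A transcript harbors the *on* form of a skipping event if it contains
the target exon(s) and both flanking introns, each endpoint within V bp
(default 10 — deliberately a separate knob from W, since assembly wobble
and annotation drift are different phenomena); it harbors the *off* form
if it contains the spanning intron within V. Retention events match the
covering exon (*on*) or the retained introns (*off*); terminal/exon-end
events match the respective variant exon. A transcript that would match
both forms — possible only when V reaches half the smallest intron
involved — is assigned to neither, with a warning.

FPKM_on is the sum of FPKM over harboring isoforms (absent FPKM
contributes 0 with a warning), R = FPKM_on/(FPKM_on+FPKM_off). R is
*undefined* — not 0 — when both sums are zero or nothing harbors either
form, so that "absent" and "expressed only as the off form" (R = 0)
remain distinguishable downstream. R uses only the on/off sums; isoforms
of the gene harboring neither form do not renormalize it.

## Cross-sample comparison

Δ = |Rᵢ − Rⱼ| with boundary semantics exactly at the printed thresholds:
Δ = 0.1 is already variable, Δ = 0.5 already a switch; undefined R on
either side makes the pair incomparable. Class fractions are reported
over the full catalog, so events quantified nowhere still occupy the
denominator. Incomparable is not subdivided into causes; a
gene-expressed flag can be emitted alongside instead. The
tissue-specificity call uses the largest pairwise difference across
samples, computed as max(R) − min(R) over defined values (provably equal
to the pairwise maximum; cross-checked against the O(n²) scan in tests);
fewer than two defined ratios yield non-switch with an
insufficient-data flag.

## Synthetic cohorts

The generator emulates the statistical shape of a multi-tissue assembly
experiment. Each gene is a backbone exon chain plus one alternate
isoform per planted event; anchors are spaced at least one backbone exon
apart and kept off the terminal exons, which guarantees (and tests
verify) that pairwise comparison of any two isoforms yields exactly the
planted events. Defaults: 16 tissue-named samples; 8–12 exons of 100–300
bp separated by 200–2000 bp introns; log-normal isoform FPKM (μ = 1,
σ = 1, floored at low positive values, written with 6 decimals — all
downstream comparisons are at that precision); per-sample isoform
presence 0.7; inclusion bias 0.75 (the exon-containing form is usually
the major one); 60% of events novel, planted by withholding the event's
alternate isoform from the emitted annotation (skipping-type events thus
get novel spanning introns, retention/exon-end events overlapping novel
exons, and alternative-start events entirely new, non-overlapping
exons); optional ≤ W jitter of annotation boundaries exercises tolerant
matching. Infeasible configurations (introns shorter than 2V, exons
shorter than the boundary shifts, a class mix not summing to 1) are
rejected before generation, and a fixed seed reproduces byte-identical
GTFs.

For cohorts with exactly one event per gene and ≥ 2 samples, a planted
class mix (default 30% stable / 10% variable / 5% switch / 55% absent)
dictates the pairwise relation between the **first two samples**: class
drawn per event, inclusion ratios constructed to realise it with a
margin from the class boundaries so 6-decimal rounding cannot recross
them; remaining samples draw independently. In multi-event genes, event
ratios within a gene are coupled through shared isoforms, so there the
generator draws isoform expression freely and the truth table records
the resulting ratios rather than planted classes. The truth table's
FPKM_on/FPKM_off are computed by structural bookkeeping (the generator
knows which isoforms carry which form) in emission order, and therefore
equal `quantify_event` output exactly at any V when no jitter is
applied. For the chain-sensitive terminal/exon-end classes, catalog
supporters are only the (backbone, alternate) pairing — other isoforms
carry the variant exon but differ elsewhere in the chain — while
quantification carriers include every harboring isoform; the truth
table tracks both.

What the generator does **not** emulate: read-level noise and mapping
artifacts (sample GTFs carry exact planted coordinates; boundary wobble
exists only in the annotation jitter and in redundancy-test fixtures),
partial/fragmented transfrags, overlapping genes, and polymorphic
variation. Passing recovery tests therefore demonstrates correctness of
the event algebra and quantification arithmetic on clean structures,
not robustness to assembler noise.

## Problem sizes

The test suite and the acceptance script run cohorts of 100 genes × 16
samples with all seven event types (≈ 700 events, ≈ 400k pair
comparisons), a 2,000-gene two-sample cohort for class-mix recovery,
1,000+ random transcript pairs for oracle equivalence, and smaller
instances for unit properties; the independent brute-force classifier
(`spliceprof.oracle`) shares definitions but no code with the production
scanner.

## Known limitations

* Mutually exclusive exons are not a class; they surface as two
  overlapping skip events.
* Terminal-exon inner-boundary variation alone is unclassified (strict
  internal-exon reading of alternative exon ends).
* Redundancy collapse keeps one representative without merging supporter
  sets across a cluster.
* The catalog TSV does not serialise supporter identities (counts only),
  so a catalog read back from disk carries empty supporter sets.
* `quantify_catalog` is O(events × samples × isoforms-per-gene); very
  large catalogs would want an interval-indexed matcher.
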