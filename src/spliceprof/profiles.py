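"""Cross-sample splicing-profile comparison ('collect-fpkm').

For an event quantified in two samples i and j, the relative inclusion
ratio is Δ = |Ri − Rj|, classified as

* ``stable``        Δ < 0.1
* ``variable``      0.1 ≤ Δ < 0.5
* ``switch``        Δ ≥ 0.5   (the major and minor forms trade places)
* ``incomparable``  R undefined in one or both samples (the event is not
  found there — typically the gene is not expressed or harbors different
  splice forms)

Class fractions are reported over the full event catalog, so events absent
from one or both samples count in the denominator. With a single sample
per condition these comparisons are qualitative; no significance testing
is attached to them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .quantify import EventQuant

__all__ = [
    "CLASSES",
    "ProfileComparison",
    "ComparisonMatrix",
    "classify_pair",
    "build_matrix",
    "max_delta_class",
]

CLASSES = ("stable", "variable", "switch", "incomparable")

# printed-threshold defaults: stable below 0.1, switch from 0.5
STABLE_MAX = 0.1
SWITCH_MIN = 0.5


def _check_ratio(r: float | None, name: str) -> None:
    if r is not None and not (0.0 <= r <= 1.0):
        raise ValueError(f"{name}={r} outside [0, 1]")


@dataclass(frozen=True)
class ProfileComparison:
    """One event compared between two samples."""

    event_id: str
    sample_i: str
    sample_j: str
    r_i: float | None
    r_j: float | None
    delta: float | None
    klass: str


def classify_pair(
    r_i: float | None,
    r_j: float | None,
    stable_max: float = STABLE_MAX,
    switch_min: float = SWITCH_MIN,
) -> tuple[float | None, str]:
    """Δ = |Ri − Rj| and its class.

    Boundary semantics follow the printed thresholds exactly: Δ equal to
    ``stable_max`` is already variable, Δ equal to ``switch_min`` is
    already a switch. Undefined R on either side yields (None,
    'incomparable').
    """
    _check_ratio(r_i, "Ri")
    _check_ratio(r_j, "Rj")
    if r_i is None or r_j is None:
        return None, "incomparable"
    delta = abs(r_i - r_j)
    if delta < stable_max:
        return delta, "stable"
    if delta < switch_min:
        return delta, "variable"
    return delta, "switch"


@dataclass
class ComparisonMatrix:
    """Per-sample-pair class counts over all catalog events.

    Counts are stored once per unordered pair and reported symmetrically;
    for every pair the four class counts sum to the catalog size.
    """

    samples: list[str]
    n_events: int
    _counts: dict[tuple[str, str], dict[str, int]] = field(default_factory=dict)

    @staticmethod
    def _key(i: str, j: str) -> tuple[str, str]:
        return (i, j) if i <= j else (j, i)

    def counts(self, i: str, j: str) -> dict[str, int]:
        return dict(self._counts.get(self._key(i, j), {k: 0 for k in CLASSES}))

    def fractions(self, i: str, j: str) -> dict[str, float]:
        c = self.counts(i, j)
        denom = self.n_events or 1
        return {k: v / denom for k, v in c.items()}

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for (i, j), c in sorted(self._counts.items()):
            rows.append({"sample_i": i, "sample_j": j, **c})
        return pd.DataFrame(
            rows, columns=["sample_i", "sample_j", *CLASSES]
        )


def build_matrix(
    quants: Mapping[tuple[str, str], EventQuant],
    samples: Sequence[str],
    event_ids: Iterable[str] | None = None,
    stable_max: float = STABLE_MAX,
    switch_min: float = SWITCH_MIN,
) -> tuple[ComparisonMatrix, list[ProfileComparison]]:
    """Classify every event between every unordered sample pair.

    ``quants`` maps (event_id, sample_id) to a quantification; missing
    combinations are treated as absent (R undefined). ``event_ids``
    defaults to all event ids present in ``quants``; supplying the full
    catalog explicitly keeps events quantified nowhere in the denominator.
    """
    if event_ids is None:
        ids = sorted({eid for eid, _ in quants})
    else:
        ids = sorted(set(event_ids))
    matrix = ComparisonMatrix(samples=list(samples), n_events=len(ids))
    comparisons: list[ProfileComparison] = []
    for si, sj in itertools.combinations(samples, 2):
        key = ComparisonMatrix._key(si, sj)
        counts = {k: 0 for k in CLASSES}
        for eid in ids:
            qi = quants.get((eid, si))
            qj = quants.get((eid, sj))
            r_i = qi.R if qi is not None else None
            r_j = qj.R if qj is not None else None
            delta, klass = classify_pair(r_i, r_j, stable_max, switch_min)
            counts[klass] += 1
            comparisons.append(
                ProfileComparison(
                    event_id=eid,
                    sample_i=si,
                    sample_j=sj,
                    r_i=r_i,
                    r_j=r_j,
                    delta=delta,
                    klass=klass,
                )
            )
        matrix._counts[key] = counts
    return matrix, comparisons


def max_delta_class(
    ratios: Iterable[float | None], switch_min: float = SWITCH_MIN
) -> tuple[str, bool]:
    """Tissue-specificity call over a set of samples: 'switch' when the
    largest pairwise |Ri − Rj| over samples with defined R reaches the
    switch threshold, else 'non-switch'.

    The maximum pairwise difference equals max(R) − min(R) over the
    defined values. Returns (class, insufficient_data): with fewer than
    two defined ratios the call is 'non-switch' with the flag set.
    """
    defined = [r for r in ratios if r is not None]
    for r in defined:
        _check_ratio(r, "R")
    if len(defined) < 2:
        return "non-switch", True
    max_delta = max(defined) - min(defined)
    return ("switch" if max_delta >= switch_min else "non-switch"), False
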