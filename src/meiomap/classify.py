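"""Assign event groups to recombination classes E1-E7 and summarize tetrads.

The classes follow the groupEvents taxonomy used for yeast tetrad
recombination maps:

* **E1** — simple noncrossover: one conversion tract on one chromatid,
  no crossover nearby.
* **E2** — simple crossover, with or without one continuous associated
  conversion tract on a crossover chromatid.
* **E3** — crossover with discontinuous conversion: one crossover plus
  additional conversion tract(s) on the crossover chromatids.
* **E4** — discontinuous noncrossover: two or more tracts on one
  chromatid separated by 2:2 segregation.
* **E5** — double crossover (E5A when both crossovers involve the same
  chromatid pair, the signature of an unbiased two-junction resolution).
* **E6** — conversions on two or more chromatids without a crossover
  (includes 4:0 tracts).
* **E7** — anything more complex (three or more crossovers, or a
  crossover with conversion on a non-crossover chromatid).

E1-E4 and E5A follow their published definitions; the E5/E6/E7
boundaries are a documented reconstruction of the remaining classes
(compatible with the original groupEvents taxonomy, not guaranteed
identical).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .calling import EventGroup, PHASE_CHANGE, RawEvent

CLASSES = ("E1", "E2", "E3", "E4", "E5", "E5A", "E6", "E7")


def classify_group(group: EventGroup) -> str:
    """Label an event group by the decision order E1/E4/E2/E3/E5/E6/E7."""
    if not group.events:
        raise ValueError("cannot classify an empty event group")
    cos = group.crossovers
    tracts = group.tracts
    if not cos:
        union = frozenset().union(*(t.chromatids for t in tracts)) if tracts else frozenset()
        if len(tracts) == 1 and len(tracts[0].chromatids) == 1:
            return "E1"
        if (
            len(tracts) >= 2
            and all(len(t.chromatids) == 1 for t in tracts)
            and len(union) == 1
        ):
            return "E4"
        if len(union) >= 2:
            return "E6"
        return "E7"
    if len(cos) == 1:
        co_chromatids = cos[0].chromatids
        if not tracts:
            return "E2"
        if all(t.chromatids <= co_chromatids for t in tracts):
            attached = [t for t in tracts if t.flank_relation == PHASE_CHANGE]
            additional = [t for t in tracts if t.flank_relation != PHASE_CHANGE]
            if not additional and len(attached) <= 1:
                return "E2"
            return "E3"
        return "E7"
    if len(cos) == 2:
        return "E5A" if cos[0].chromatids == cos[1].chromatids else "E5"
    return "E7"


@dataclass(frozen=True)
class TractLength:
    """Minimal / midpoint / maximal tract-length estimates (bp).

    ``min`` spans the converted markers only, ``max`` the nearest
    flanking unconverted informative markers, ``mid`` their average.
    ``edge`` flags tracts at a chromosome end where only one flank
    exists (``max`` then extends on the flanked side only).
    """

    min: float
    mid: float
    max: float
    edge: bool = False


def tract_length(tract: RawEvent) -> TractLength:
    """Tract-length estimates from marker geometry."""
    lo = float(tract.end - tract.start)
    left, right = tract.left_flank, tract.right_flank
    if left is not None and right is not None:
        hi = float(right - left)
        edge = False
    elif right is not None:
        hi = float(right - tract.start)
        edge = True
    elif left is not None:
        hi = float(tract.end - left)
        edge = True
    else:
        hi = lo
        edge = True
    return TractLength(lo, (lo + hi) / 2.0, hi, edge)


@dataclass
class TetradEventSummary:
    """Per-tetrad class counts with the derived totals.

    CO = E2+E3, NCO = E1, NCO_disc = E4; IH_total sums every
    interhomolog class (E5A counted within the E5 family).
    """

    tetrad_id: str
    counts: dict = field(default_factory=lambda: {c: 0 for c in CLASSES})

    @property
    def co(self) -> int:
        return self.counts["E2"] + self.counts["E3"]

    @property
    def nco(self) -> int:
        return self.counts["E1"]

    @property
    def nco_disc(self) -> int:
        return self.counts["E4"]

    @property
    def ih_total(self) -> int:
        return sum(self.counts.values())

    def as_row(self) -> dict:
        row = {"tetrad_id": self.tetrad_id, **self.counts}
        row.update(CO=self.co, NCO=self.nco, NCO_disc=self.nco_disc,
                   IH_total=self.ih_total)
        return row


def summarize(tetrad_id: str, groups: list[EventGroup]) -> TetradEventSummary:
    """Count classified groups per class for one tetrad."""
    summary = TetradEventSummary(tetrad_id)
    for g in groups:
        if g.label is None:
            raise ValueError("all groups must be classified before summarizing")
        summary.counts[g.label] += 1
    return summary


def summary_table(summaries: list[TetradEventSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.as_row() for s in summaries])
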