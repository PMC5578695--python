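"""Call raw recombination events from a tetrad's segregation profile.

Two signals are read off the marker-by-marker segregation pattern:

* **Gene-conversion tracts** — maximal runs of markers deviating from 2:2
  segregation.  The converted chromatid(s) are the spores whose call
  differs from their inferred parental phase, inferred from the nearest
  informative 2:2 marker on each side (parsimony between the two sides
  when they disagree).
* **Crossovers** — a change of 2:2 phase between adjacent informative
  markers.  A Hamming distance of 2 between the P1-spore sets is one
  crossover on the two switching chromatids; distance 4 is a four-strand
  double crossover (two events).  A phase change across a conversion
  tract is the crossover associated with that tract and is attached to
  the tract's interval.

Markers masked as INCOMPLETE are neutral gaps: they neither break nor
join runs and carry no phase information.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core import MISSING, P1, SegregationProfile

CO = "CO"
GC_TRACT = "GC_TRACT"

SAME_PHASE = "SAME_PHASE"
PHASE_CHANGE = "PHASE_CHANGE"
EDGE = "EDGE"


@dataclass(frozen=True)
class RawEvent:
    """One called crossover or gene-conversion tract.

    ``start``/``end`` are 1-based marker positions: for a CO, the two
    flanking informative markers bracketing the breakpoint (zero
    converted markers inside); for a tract, the first and last converted
    markers.  ``left_flank``/``right_flank`` are the nearest informative
    unconverted 2:2 marker positions (``None`` at a chromosome edge).
    """

    chrom: str
    kind: str
    chromatids: frozenset
    start: int
    end: int
    flank_relation: str | None = None
    left_flank: int | None = None
    right_flank: int | None = None

    def footprint(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class EventGroup:
    """Nearby raw events merged at the grouping gap (single linkage)."""

    chrom: str
    events: tuple[RawEvent, ...]
    label: str | None = None

    @property
    def span(self) -> tuple[int, int]:
        return (min(e.start for e in self.events), max(e.end for e in self.events))

    @property
    def crossovers(self) -> list[RawEvent]:
        return [e for e in self.events if e.kind == CO]

    @property
    def tracts(self) -> list[RawEvent]:
        return [e for e in self.events if e.kind == GC_TRACT]


def _pair_double_co(left: frozenset, right: frozenset) -> list[frozenset]:
    """Chromatid pairs for a Hamming-4 phase change (two crossovers)."""
    leaves = sorted(left - right)
    enters = sorted(right - left)
    return [frozenset({leaves[0], enters[0]}), frozenset({leaves[1], enters[1]})]


def _converted_spores(
    calls: np.ndarray, left: frozenset | None, right: frozenset | None
) -> frozenset:
    """Spores whose call deviates from the inferred parental phase.

    The deviation set is computed against each available flank and the
    union returned.  When the flanks agree (or only one exists) this is
    simply the set of deviating spores.  When the flanks differ — a
    crossover-associated tract — the conversion lies on one of the two
    switching strands but the data cannot say which (the junction may
    sit at either tract edge), so both candidates are reported and the
    tract's chromatids coincide with the crossover pair.
    """
    union: frozenset = frozenset()
    seen = []
    for phase in (left, right):
        if phase is None or phase in seen:
            continue
        seen.append(phase)
        expected_p1 = np.zeros(4, dtype=bool)
        expected_p1[list(phase)] = True
        observed_p1 = calls == P1
        union |= frozenset(np.flatnonzero(observed_p1 != expected_p1).tolist())
    return union


def call_raw_events(
    profile: SegregationProfile, matrix: np.ndarray
) -> list[RawEvent]:
    """Extract crossovers and conversion tracts from one chromosome.

    ``matrix`` is the tetrad's 4 x M call matrix aligned with the
    profile.  Conversion tracts are maximal runs of consecutive
    non-2:2 markers (a masked/INCOMPLETE marker separates runs but
    carries no phase information); crossovers are phase changes between
    consecutive informative 2:2 markers, attached to the first
    intervening tract when one exists.  A chromosome with fewer than two
    informative 2:2 markers yields an empty list with a warning (no
    phase can be established).
    """
    if matrix.shape != (4, len(profile)):
        raise ValueError("matrix not aligned with profile")
    pos = profile.positions
    complete = np.all(matrix != MISSING, axis=0)
    n1 = np.sum(matrix == P1, axis=0)
    is22 = complete & (n1 == 2)
    info22 = np.flatnonzero(is22)
    if info22.size < 2:
        warnings.warn(
            f"{profile.chrom}: fewer than 2 informative 2:2 markers; no events called"
        )
        return []

    # maximal runs of consecutive informative non-2:2 markers
    non22 = np.flatnonzero(complete & ~is22)
    runs: list[np.ndarray] = (
        np.split(non22, np.flatnonzero(np.diff(non22) > 1) + 1)
        if non22.size
        else []
    )

    def phase_at(j: int) -> frozenset:
        return frozenset(np.flatnonzero(matrix[:, j] == P1).tolist())

    def emit_co(left: frozenset, right: frozenset, interval, lf=None, rf=None):
        diff = left ^ right
        if len(diff) == 2:
            pairs = [diff]
        else:
            pairs = _pair_double_co(left, right)
        for pair in pairs:
            events.append(
                RawEvent(profile.chrom, CO, pair, interval[0], interval[1], None, lf, rf)
            )

    events: list[RawEvent] = []

    # tracts, with phase inferred from the nearest informative 2:2 marker
    # on each side
    for run in runs:
        i = int(np.searchsorted(info22, run[0]))
        jl = int(info22[i - 1]) if i > 0 else None
        k = int(np.searchsorted(info22, run[-1], side="right"))
        jr = int(info22[k]) if k < info22.size else None
        left_phase = phase_at(jl) if jl is not None else None
        right_phase = phase_at(jr) if jr is not None else None
        chromatids: frozenset = frozenset()
        for j in run:
            chromatids |= _converted_spores(matrix[:, j], left_phase, right_phase)
        if left_phase is None or right_phase is None:
            relation = EDGE
        elif left_phase == right_phase:
            relation = SAME_PHASE
        else:
            relation = PHASE_CHANGE
        start, end = int(pos[run[0]]), int(pos[run[-1]])
        lf = int(pos[jl]) if jl is not None else None
        rf = int(pos[jr]) if jr is not None else None
        events.append(
            RawEvent(profile.chrom, GC_TRACT, chromatids, start, end, relation, lf, rf)
        )

    # crossovers between consecutive informative 2:2 markers; when tracts
    # lie in between, the crossover is attached to the first tract's
    # interval (one crossover per phase change, however many runs)
    codes = (matrix[:, info22] == P1).T.astype(np.int8) @ np.array([1, 2, 4, 8], np.int8)
    changed = np.flatnonzero(codes[1:] != codes[:-1])
    for c in changed:
        ja, jb = int(info22[c]), int(info22[c + 1])
        pa, pb = phase_at(ja), phase_at(jb)
        between = [r for r in runs if r[0] > ja and r[-1] < jb]
        if between:
            first = between[0]
            interval = (int(pos[first[0]]), int(pos[first[-1]]))
            emit_co(pa, pb, interval, int(pos[ja]), int(pos[jb]))
        else:
            emit_co(pa, pb, (int(pos[ja]), int(pos[jb])))

    events.sort(key=lambda e: (e.start, e.end, e.kind))
    return events


def group_events(
    events: Iterable[RawEvent], gap: int = 5000
) -> list[EventGroup]:
    """Merge events whose footprints lie within ``gap`` bp (single linkage).

    Two events join one group iff the distance between their nearest
    footprint coordinates is at most ``gap``; groups are maximal under
    transitive closure.  Input order is immaterial.
    """
    if gap < 0:
        raise ValueError("grouping gap must be >= 0")
    by_chrom: dict[str, list[RawEvent]] = {}
    for e in events:
        by_chrom.setdefault(e.chrom, []).append(e)
    groups: list[EventGroup] = []
    for chrom in sorted(by_chrom):
        evs = sorted(by_chrom[chrom], key=lambda e: (e.start, e.end, e.kind))
        current: list[RawEvent] = []
        reach = -np.inf
        for e in evs:
            if current and e.start - reach > gap:
                groups.append(EventGroup(chrom, tuple(current)))
                current = []
                reach = -np.inf
            current.append(e)
            reach = max(reach, e.end)
        if current:
            groups.append(EventGroup(chrom, tuple(current)))
    return groups


def relabel_spores(event: RawEvent, perm: Sequence[int]) -> RawEvent:
    """Apply a spore permutation to an event's chromatid indices."""
    return RawEvent(
        event.chrom,
        event.kind,
        frozenset(perm[i] for i in event.chromatids),
        event.start,
        event.end,
        event.flank_relation,
        event.left_flank,
        event.right_flank,
    )
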