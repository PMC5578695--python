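"""Brute-force enumeration oracle for event classification.

Independent of the production caller/classifier: tetrads on a 6-marker
scaffold are generated from planted events (crossovers with optional
attached conversion tracts, and noncrossover conversions) by a tiny
stand-alone painter, and the expected class labels are derived directly
from the event-class definitions applied to the planted configuration:

* E1 simple NCO, E4 two or more NCO tracts on one chromatid separated by
  2:2 markers, E6 conversions on two or more chromatids without a
  crossover;
* E2 one crossover with at most one continuous conversion run on its
  chromatids, E3 one crossover with discontinuous conversion on its
  chromatids, E7 a crossover with conversion on a non-crossover
  chromatid;
* E5 two crossovers (E5A when both involve the same strand pair).

Because sparse markers make distinct truths observationally identical,
the oracle labels a matrix by enumerating *all* cataloged explanations
painting to that matrix, keeping those with the fewest events, and
collecting their label multisets; an implementation agrees when its
labels match one of them (almost always unique).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

MARKERS = np.array([1000, 3000, 5000, 7000, 9000, 11000], dtype=np.int64)
N_MARKERS = 6
CHROM_LEN = 13000
GROUP_GAP = 5000

#: spore pairs that cross the founding 2:2 phase ({0,1} P1 / {2,3} P2)
FIRST_PAIRS = ((0, 2), (0, 3), (1, 2), (1, 3))


@dataclass(frozen=True)
class PlantedCO:
    """Crossover in marker gap ``gap`` (between markers gap and gap+1).

    ``k`` > 0 attaches a conversion tract covering the ``k`` markers
    adjacent to the breakpoint on ``side`` ('L' or 'R'), overwriting
    strand ``recipient`` (one of ``pair``).
    """

    gap: int
    pair: tuple[int, int]
    side: str | None = None
    k: int = 0
    recipient: int | None = None

    @property
    def converted(self) -> frozenset:
        if self.k == 0:
            return frozenset()
        if self.side == "R":
            return frozenset(range(self.gap + 1, self.gap + 1 + self.k))
        return frozenset(range(self.gap - self.k + 1, self.gap + 1))

    @property
    def footprint(self) -> tuple[int, int]:
        if self.k:
            idx = sorted(self.converted)
            return (int(MARKERS[idx[0]]), int(MARKERS[idx[-1]]))
        return (int(MARKERS[self.gap]), int(MARKERS[self.gap + 1]))


@dataclass(frozen=True)
class PlantedNCO:
    """Conversion tract covering markers i..j on one strand."""

    i: int
    j: int
    chromatid: int

    @property
    def converted(self) -> frozenset:
        return frozenset(range(self.i, self.j + 1))

    @property
    def footprint(self) -> tuple[int, int]:
        return (int(MARKERS[self.i]), int(MARKERS[self.j]))


Explanation = tuple


def paint(events: Explanation) -> np.ndarray:
    """Realize planted events as a 4 x 6 call matrix (1 = P1, 2 = P2)."""
    mat = np.empty((4, N_MARKERS), dtype=np.int8)
    mat[0:2] = 1
    mat[2:4] = 2
    cos = [e for e in events if isinstance(e, PlantedCO)]
    cos.sort(key=lambda e: e.gap)
    for e in cos:
        a, b = e.pair
        cols = slice(e.gap + 1, N_MARKERS)
        tmp = mat[a, cols].copy()
        mat[a, cols] = mat[b, cols]
        mat[b, cols] = tmp
    for e in events:
        if isinstance(e, PlantedCO) and e.k:
            conv = (e.recipient, e.converted)
        elif isinstance(e, PlantedNCO):
            conv = (e.chromatid, e.converted)
        else:
            continue
        c, cols = conv
        for j in cols:
            mat[c, j] = 3 - mat[c, j]
    return mat


def _converted_union(events: Explanation) -> frozenset:
    out: frozenset = frozenset()
    for e in events:
        out |= e.converted
    return out


def is_valid(events: Explanation) -> bool:
    """Reject configurations no caller could read from segregation data.

    Conversions must not hit the same marker twice; at least two markers
    must stay 2:2 (phase needs two informative markers); every
    breakpoint needs an unconverted marker on each side; two breakpoints
    in different gaps need an unconverted marker between them.
    """
    conv_sets = [e.converted for e in events]
    for a, b in itertools.combinations(conv_sets, 2):
        if a & b:
            return False
    union = _converted_union(events)
    if N_MARKERS - len(union) < 2:
        return False
    cos = [e for e in events if isinstance(e, PlantedCO)]
    for e in cos:
        if not any(m <= e.gap and m not in union for m in range(N_MARKERS)):
            return False
        if not any(m > e.gap and m not in union for m in range(N_MARKERS)):
            return False
    for a, b in itertools.combinations(cos, 2):
        g1, g2 = sorted((a.gap, b.gap))
        between = range(g1 + 1, g2 + 1)
        if len(list(between)) and not any(m not in union for m in between):
            return False
    # each crossover must cross the running phase (one strand leaves the
    # current P1 set, one enters), else its exchange is between strands of
    # identical distal content and no reader could infer it
    phase = {0, 1}
    for e in sorted(cos, key=lambda e: e.gap):
        a, b = e.pair
        if (a in phase) == (b in phase):
            return False
        leaving = a if a in phase else b
        entering = b if leaving == a else a
        phase = (phase - {leaving}) | {entering}
    return True


def _runs(markerset: frozenset) -> list[frozenset]:
    """Maximal contiguous runs in a set of marker indices."""
    runs: list[list[int]] = []
    for m in sorted(markerset):
        if runs and m == runs[-1][-1] + 1:
            runs[-1].append(m)
        else:
            runs.append([m])
    return [frozenset(r) for r in runs]


def _label_part(events: Explanation) -> str:
    cos = [e for e in events if isinstance(e, PlantedCO)]
    convs = [
        (e.recipient, e.converted) if isinstance(e, PlantedCO) else
        (e.chromatid, e.converted)
        for e in events
        if (isinstance(e, PlantedCO) and e.k) or isinstance(e, PlantedNCO)
    ]
    chroms = {c for c, _ in convs}
    union = frozenset().union(*(s for _, s in convs)) if convs else frozenset()
    runs = _runs(union)
    if not cos:
        if len(chroms) >= 2:
            return "E6"
        return "E1" if len(runs) == 1 else "E4"
    if len(cos) == 1:
        if not convs:
            return "E2"
        if chroms <= set(cos[0].pair):
            # the crossover's own tract is the run touching its breakpoint;
            # any further (or detached) conversion makes it discontinuous
            gap = cos[0].gap
            adjacent = [r for r in runs if gap in r or gap + 1 in r]
            if len(runs) == 1 and len(adjacent) == 1:
                return "E2"
            return "E3"
        return "E7"
    if len(cos) == 2:
        return "E5A" if set(cos[0].pair) == set(cos[1].pair) else "E5"
    return "E7"


def label_explanation(events: Explanation) -> tuple[str, ...]:
    """Sorted class labels of an explanation, one per 5 kb event group."""
    if not events:
        return ()
    if len(events) == 1:
        return (_label_part(events),)
    (s1, e1), (s2, e2) = events[0].footprint, events[1].footprint
    dist = max(0, max(s1, s2) - min(e1, e2))
    if dist <= GROUP_GAP:
        return (_label_part(events),)
    return tuple(sorted((_label_part(events[:1]), _label_part(events[1:]))))


def singles_catalog() -> list[Explanation]:
    """All single-event explanations on the scaffold."""
    out: list[Explanation] = []
    for gap in range(N_MARKERS - 1):
        for pair in FIRST_PAIRS:
            out.append((PlantedCO(gap, pair),))
            for side, kmax in (("L", gap), ("R", N_MARKERS - 2 - gap)):
                for k in range(1, kmax + 1):
                    for recipient in pair:
                        out.append(
                            (PlantedCO(gap, pair, side, k, recipient),)
                        )
    for i in range(N_MARKERS):
        for j in range(i, N_MARKERS):
            for c in range(4):
                out.append((PlantedNCO(i, j, c),))
    return [e for e in out if is_valid(e)]


def pair_pool() -> list:
    """Restricted event pool for two-event explanations."""
    pool: list = []
    for gap in range(N_MARKERS - 1):
        for pair in FIRST_PAIRS:
            pool.append(PlantedCO(gap, pair))
            for side, avail in (("L", gap), ("R", N_MARKERS - 2 - gap)):
                if avail >= 1:
                    for recipient in pair:
                        pool.append(PlantedCO(gap, pair, side, 1, recipient))
    for i in range(N_MARKERS):
        for j in range(i, min(i + 2, N_MARKERS - 1) + 1):
            for c in range(4):
                pool.append(PlantedNCO(i, j, c))
    return pool


def enumerate_cases() -> list[Explanation]:
    """Every valid planted configuration with at most two events."""
    cases = singles_catalog()
    for a, b in itertools.combinations(pair_pool(), 2):
        exp = (a, b)
        if is_valid(exp):
            cases.append(exp)
    return cases


def build_oracle() -> dict[bytes, set[tuple[str, ...]]]:
    """Map each reachable matrix to the labels of its minimal explanations."""
    best: dict[bytes, tuple[int, set]] = {}
    empty = paint(()).tobytes()
    best[empty] = (0, {()})
    for exp in enumerate_cases():
        key = paint(exp).tobytes()
        n = len(exp)
        labels = label_explanation(exp)
        if key not in best or n < best[key][0]:
            best[key] = (n, {labels})
        elif n == best[key][0]:
            best[key][1].add(labels)
    return {k: v[1] for k, v in best.items()}
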