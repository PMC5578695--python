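"""Raw event calling and 5 kb single-linkage grouping."""

import itertools
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meiomap.calling import (
    CO,
    EDGE,
    GC_TRACT,
    PHASE_CHANGE,
    SAME_PHASE,
    RawEvent,
    call_raw_events,
    group_events,
    relabel_spores,
)
from meiomap.core import MISSING, P1, P2, MarkerMap, Tetrad, build_profile


def _call(mat, positions):
    mat = np.asarray(mat, dtype=np.int8)
    markers = MarkerMap({"c": np.asarray(positions)})
    profile = build_profile(Tetrad("t", {"c": mat}), "c", markers)
    return call_raw_events(profile, mat)


S, Y = P1, P2  # shorthand: parental call codes


class TestCallRawEvents:
    def test_phase_change_emits_one_co(self):
        """Phases {0,1},{0,1},{0,2},{0,2}: spores 1 and 2 switch between
        markers 2 and 3 — one CO on chromatids {1,2}."""
        mat = [
            [S, S, S, S],
            [S, S, Y, Y],
            [Y, Y, S, S],
            [Y, Y, Y, Y],
        ]
        events = _call(mat, [1000, 2000, 3000, 4000])
        assert len(events) == 1
        co = events[0]
        assert co.kind == CO
        assert co.chromatids == frozenset({1, 2})
        assert (co.start, co.end) == (2000, 3000)

    def test_same_phase_tract_on_deviating_spore(self):
        """2:2, 3:1, 2:2 with constant flanking phase: one tract on the
        spore whose call deviates from its parental expectation."""
        mat = [
            [S, S, S],
            [S, S, S],
            [Y, S, Y],
            [Y, Y, Y],
        ]
        events = _call(mat, [1000, 2000, 3000])
        assert len(events) == 1
        tract = events[0]
        assert tract.kind == GC_TRACT
        assert tract.chromatids == frozenset({2})
        assert tract.flank_relation == SAME_PHASE
        assert (tract.start, tract.end) == (2000, 2000)
        assert (tract.left_flank, tract.right_flank) == (1000, 3000)

    def test_constant_phase_is_empty(self):
        mat = [[S] * 4, [S] * 4, [Y] * 4, [Y] * 4]
        assert _call(mat, [1000, 2000, 3000, 4000]) == []

    def test_fewer_than_two_informative_22_warns_empty(self):
        mat = [
            [S, S],
            [S, S],
            [S, Y],
            [Y, Y],
        ]
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            events = _call(mat, [1000, 2000])
        assert events == []
        assert any("informative" in str(w.message) for w in caught)

    def test_hamming4_change_emits_two_cos(self):
        """Full phase reversal between adjacent markers is a four-strand
        double crossover: two COs in the same interval."""
        mat = [
            [S, Y],
            [S, Y],
            [Y, S],
            [Y, S],
        ]
        events = _call(mat, [1000, 2000])
        cos = [e for e in events if e.kind == CO]
        assert len(cos) == 2
        assert frozenset().union(*(c.chromatids for c in cos)) == frozenset(
            {0, 1, 2, 3}
        )

    def test_co_associated_tract_reports_candidate_pair(self):
        """A tract whose flanks change phase carries the CO: the converted
        strand is ambiguous between the two switching strands, so the
        tract reports both and the CO is attached to its interval."""
        # CO (0,2): phase {0,1} at m0, {1,2} at m3; conversion at m1
        # (spore 2 carries P1 one marker early)
        mat = [
            [S, S, Y, Y],
            [S, S, S, S],
            [Y, S, S, S],
            [Y, Y, Y, Y],
        ]
        events = _call(mat, [1000, 2000, 3000, 4000])
        kinds = sorted(e.kind for e in events)
        assert kinds == [CO, GC_TRACT]
        tract = next(e for e in events if e.kind == GC_TRACT)
        co = next(e for e in events if e.kind == CO)
        assert tract.flank_relation == PHASE_CHANGE
        assert co.chromatids == frozenset({0, 2})
        assert tract.chromatids == frozenset({0, 2})
        assert (co.start, co.end) == (tract.start, tract.end)

    def test_edge_tract_uses_single_flank(self):
        # first marker deviates (1:3), no 2:2 marker to its left
        mat = [
            [Y, S, S],
            [S, S, S],
            [Y, Y, Y],
            [Y, Y, Y],
        ]
        events = _call(mat, [1000, 2000, 3000])
        assert len(events) == 1
        tract = events[0]
        assert tract.flank_relation == EDGE
        assert tract.left_flank is None and tract.right_flank == 2000
        assert tract.chromatids == frozenset({0})

    def test_incomplete_markers_are_neutral_gaps(self):
        """A masked marker neither breaks phase nor joins tracts."""
        mat = np.array(
            [
                [S, S, S, S, S],
                [S, S, S, S, S],
                [Y, S, MISSING, S, Y],
                [Y, Y, Y, Y, Y],
            ],
            dtype=np.int8,
        )
        events = _call(mat, [1000, 2000, 3000, 4000, 5000])
        tracts = [e for e in events if e.kind == GC_TRACT]
        assert len(tracts) == 2  # not joined across the masked marker
        assert all(t.chromatids == frozenset({2}) for t in tracts)
        assert not any(e.kind == CO for e in events)

    def test_spore_relabelling_equivariance(self, rng):
        """Permuting spore rows permutes called chromatids and nothing else."""
        from meiomap import SimParams, GenomeMap, simulate_batch

        params = SimParams(
            mean_co_per_meiosis=8, mean_detectable_nco=5,
            marker_spacing_mean=800, seed=3,
        )
        genome = GenomeMap((("c", 300_000),))
        markers, (tetrad,), _ = simulate_batch(params, genome, 1)
        perm = [2, 0, 3, 1]
        base = call_raw_events(
            build_profile(tetrad, "c", markers), tetrad.matrix("c")
        )
        permuted_mat = tetrad.matrix("c")[np.argsort(perm)]
        permuted = call_raw_events(
            build_profile(Tetrad("p", {"c": permuted_mat}), "c", markers),
            permuted_mat,
        )
        # relabel base events into the permuted coordinate system
        inv = {old: new for new, old in enumerate(np.argsort(perm))}
        expected = sorted(
            (e.kind, e.start, e.end, tuple(sorted(inv[i] for i in e.chromatids)))
            for e in base
        )
        got = sorted(
            (e.kind, e.start, e.end, tuple(sorted(e.chromatids)))
            for e in permuted
        )
        assert got == expected


def _ev(chrom, start, end, kind=GC_TRACT):
    return RawEvent(chrom, kind, frozenset({0}), start, end, SAME_PHASE)


class TestGroupEvents:
    def test_within_gap_merges(self):
        groups = group_events([_ev("c", 2000, 2000), _ev("c", 6400, 6400)])
        assert len(groups) == 1

    def test_beyond_gap_splits(self):
        groups = group_events([_ev("c", 2000, 2000), _ev("c", 8000, 8000)])
        assert len(groups) == 2

    def test_chromosomes_never_merge(self):
        groups = group_events([_ev("a", 100, 100), _ev("b", 100, 100)])
        assert len(groups) == 2

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            group_events([], gap=-1)

    @settings(max_examples=60, derandomize=True)
    @given(
        st.lists(
            st.tuples(st.integers(0, 60_000), st.integers(0, 4000)),
            min_size=1,
            max_size=12,
        )
    )
    def test_matches_brute_force_transitive_closure(self, spans):
        """Single-linkage grouping equals O(n^2) transitive closure."""
        events = [_ev("c", s, s + w) for s, w in spans]
        groups = group_events(events, gap=5000)

        def near(a, b):
            return max(a.start, b.start) - min(a.end, b.end) <= 5000

        n = len(events)
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i, j in itertools.combinations(range(n), 2):
            if near(events[i], events[j]):
                parent[find(i)] = find(j)
        expected = {}
        for i in range(n):
            expected.setdefault(find(i), []).append(events[i])
        got = sorted(
            sorted((e.start, e.end) for e in g.events) for g in groups
        )
        want = sorted(
            sorted((e.start, e.end) for e in grp) for grp in expected.values()
        )
        assert got == want

    def test_input_order_irrelevant(self):
        events = [
            _ev("c", 100, 200),
            _ev("c", 4000, 4100),
            _ev("c", 20_000, 20_500),
        ]
        a = group_events(events)
        b = group_events(events[::-1])
        assert [g.span for g in a] == [g.span for g in b]


def test_relabel_spores_helper():
    e = RawEvent("c", CO, frozenset({0, 2}), 10, 20)
    out = relabel_spores(e, [3, 2, 1, 0])
    assert out.chromatids == frozenset({1, 3})
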