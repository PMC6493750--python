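"""Movement matching, frameshift compensation, occupancy and death calls."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wormarena.detect import WormObject
from wormarena.vitality import (
    DeathCall,
    MatchResult,
    call_death,
    classify_occupancy,
    compensate_global_shift,
    compute_yield,
    match_objects,
    movement_table,
    moving_count,
    occupancy_breakdown,
)


def obj(r, c, arena=0, t=0.0, area=400):
    return WormObject(arena=arena, time_h=t, area=area, centroid=(float(r), float(c)),
                      bbox_height=10, bbox_width=40)


class TestMatchObjects:
    def test_static_object_matches_with_zero_displacement(self):
        m = match_objects([obj(10, 10)], [obj(10, 10)])
        assert m.pairs == [(0, 0)]
        assert m.displacements[0] == 0.0
        assert m.appeared == m.disappeared == []

    def test_three_four_five_triangle(self):
        m = match_objects([obj(10, 10)], [obj(13, 14)])
        assert m.displacements[0] == 5.0

    def test_two_versus_one_keeps_nearest(self):
        m = match_objects([obj(10, 10), obj(40, 40)], [obj(11, 11)])
        assert m.pairs == [(0, 0)]
        assert m.disappeared == [1]
        assert m.appeared == []

    def test_agrees_with_optimal_assignment_on_sparse_cases(self):
        # exhaustive min-total-distance assignment agrees with greedy
        # matching when objects are well separated between frames
        rng = np.random.default_rng(8)
        for _ in range(50):
            n_p, n_c = int(rng.integers(1, 4)), int(rng.integers(1, 4))
            # well-separated base positions (pairwise distance >> jitter)
            while True:
                base = rng.uniform(20, 400, size=(max(n_p, n_c), 2)) * np.array([0.25, 1.0])
                d = np.linalg.norm(base[:, None] - base[None, :], axis=2)
                if len(base) == 1 or d[np.triu_indices(len(base), 1)].min() > 40:
                    break
            prev = [obj(*p) for p in base[:n_p]]
            curr = [obj(*(p + rng.uniform(-5, 5, 2))) for p in base[:n_c]]
            m = match_objects(prev, curr)
            k = min(n_p, n_c)
            best = None
            for pi in itertools.permutations(range(n_p), k):
                for ci in itertools.permutations(range(n_c), k):
                    cost = sum(
                        math.dist(prev[i].centroid, curr[j].centroid)
                        for i, j in zip(pi, ci)
                    )
                    if best is None or cost < best[0]:
                        best = (cost, set(zip(pi, ci)))
            assert set(m.pairs) == best[1]


def _match_with_vectors(vectors):
    vectors = np.atleast_2d(np.asarray(vectors, float)) if len(vectors) else np.zeros((0, 2))
    return MatchResult(
        pairs=[(i, i) for i in range(len(vectors))],
        vectors=vectors,
        disappeared=[],
        appeared=[],
        n_prev=len(vectors),
        n_curr=len(vectors),
    )


class TestCompensateGlobalShift:
    # five arenas whose per-arena vectors have an exactly zero median
    BASE = [[(1.0, 0.0)], [(-1.0, 0.0)], [(0.0, 1.0)], [(0.0, -1.0)], [(0.0, 0.0)]]

    def test_quiet_array_unchanged(self):
        matches = [_match_with_vectors(v) for v in self.BASE]
        out, flagged, vec = compensate_global_shift(matches)
        assert not flagged
        for m_in, m_out in zip(matches, out):
            np.testing.assert_array_equal(m_in.vectors, m_out.vectors)

    def test_uniform_shift_detected_and_inverted(self):
        shifted = [_match_with_vectors(np.asarray(v) + [10.0, 0.0]) for v in self.BASE]
        out, flagged, vec = compensate_global_shift(shifted)
        assert flagged
        np.testing.assert_allclose(vec, [10.0, 0.0], atol=1e-9)
        for orig, m in zip(self.BASE, out):
            np.testing.assert_allclose(m.vectors, orig, atol=1e-9)

    def test_single_moving_arena_is_not_a_frameshift(self):
        matches = [_match_with_vectors([(10.0, 0.0)])] + [
            _match_with_vectors([(0.0, 0.0)]) for _ in range(4)
        ]
        out, flagged, _ = compensate_global_shift(matches)
        assert not flagged
        np.testing.assert_array_equal(out[0].vectors, [[10.0, 0.0]])

    def test_no_quorum_below_three_arenas(self):
        matches = [_match_with_vectors([(10.0, 0.0)]), _match_with_vectors([(10.0, 0.0)])]
        _, flagged, _ = compensate_global_shift(matches)
        assert not flagged


class TestMovingCount:
    def test_exact_threshold_is_not_moving(self):
        m = _match_with_vectors([(7.0, 0.0)])
        assert moving_count(m, move_threshold=7.0) == 0

    def test_strictly_greater_counts(self):
        m = _match_with_vectors([(8.0, 0.0), (2.0, 0.0)])
        assert moving_count(m) == 1

    def test_disappearance_counts_as_movement(self):
        m = MatchResult([], np.zeros((0, 2)), disappeared=[0], appeared=[], n_prev=1, n_curr=0)
        assert moving_count(m) == 1

    def test_capped_at_pair_object_count(self):
        m = MatchResult(
            [(0, 0)], np.array([[9.0, 0.0]]), disappeared=[1], appeared=[1],
            n_prev=2, n_curr=2,
        )
        assert moving_count(m) == 2


class TestClassifyOccupancy:
    def test_constant_single(self):
        occ = classify_occupancy(np.ones(11, int), np.arange(11.0))
        assert occ.label == "1" and not occ.excluded

    def test_mode_wins(self):
        counts = [1, 1, 2, 1, 1, 1, 1, 1, 1, 1, 1]
        assert classify_occupancy(counts, np.arange(11.0)).label == "1"

    def test_tie_breaks_toward_larger(self):
        counts = [1, 2, 1, 2, 1, 2, 0, 0, 0, 0, 0]
        times = np.arange(11.0)
        # window [0, 10]: six frames of 1/2 tie 3-3 plus five 0s... build a real tie
        counts = [1, 1, 1, 2, 2, 2, 0, 0, 0, 0, 0]
        occ = classify_occupancy(counts[:6], times[:6], window_h=10)
        assert occ.label == "2"

    def test_four_plus_excluded(self):
        counts = [4, 4, 5, 4, 4, 4, 4, 4, 4, 4, 4]
        occ = classify_occupancy(counts, np.arange(11.0))
        assert occ.label == "4+" and occ.excluded

    def test_short_series_warns_and_uses_all(self):
        with pytest.warns(UserWarning, match="window"):
            occ = classify_occupancy([2, 2, 2], np.arange(3.0), window_h=10)
        assert occ.label == "2"


def forward_death_oracle(times, counts, quiescent_h=4.0, confirm_m=2):
    """Independent forward state machine implementing the printed rule:
    death = last movement before the first quiescent run spanning the
    required hours; movement after a qualifying run must be confirmed over
    >= confirm_m consecutive frames to reset the scan."""
    times = list(times)
    counts = list(counts)
    if times[-1] - times[0] < quiescent_h:
        return ("censored", times[-1])
    dt = float(np.median(np.diff(times)))
    needed = max(1, math.ceil(quiescent_h / dt))
    anchor = None
    qualified = False
    i = 0
    n = len(counts)
    while i < n:
        j = i
        while j < n and (counts[j] > 0) == (counts[i] > 0):
            j += 1
        run_len = j - i
        if counts[i] > 0:
            if not qualified:
                anchor = j - 1
            elif run_len >= confirm_m:
                qualified = False
                anchor = j - 1
        else:
            if not qualified and run_len >= needed:
                qualified = True
        i = j
    if qualified:
        return ("dead", times[anchor] if anchor is not None else times[0])
    return ("censored", times[-1])


class TestCallDeath:
    def test_simple_quiescence(self):
        call = call_death(np.arange(9.0), [1, 1, 1, 0, 0, 0, 0, 0, 0])
        assert (call.status, call.time_h) == ("dead", 2.0)

    def test_moving_to_the_end_is_censored(self):
        call = call_death(np.arange(9.0), [1] * 9)
        assert (call.status, call.time_h) == ("censored", 8.0)

    def test_single_late_blip_is_spurious(self):
        call = call_death(np.arange(13.0), [1, 1, 1, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0])
        assert (call.status, call.time_h) == ("dead", 2.0)

    def test_confirmed_movement_resets_short_quiet_run(self):
        call = call_death(np.arange(12.0), [1, 1, 1, 0, 0, 1, 1, 0, 0, 0, 0, 0])
        assert (call.status, call.time_h) == ("dead", 6.0)

    def test_confirmed_movement_after_qualifying_run_resets(self):
        counts = [1, 1, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1]
        call = call_death(np.arange(12.0), counts)
        assert call.status == "censored"

    def test_never_moving_arena_dies_at_start(self):
        call = call_death(np.arange(9.0), [0] * 9)
        assert (call.status, call.time_h) == ("dead", 0.0)

    def test_short_series_censored_with_warning(self):
        with pytest.warns(UserWarning, match="shorter"):
            call = call_death(np.array([0.0, 1.0, 2.0]), [1, 0, 0])
        assert call.status == "censored"

    def test_subhourly_sampling_converts_quiescence_to_frames(self):
        # 30-min scans: 4 h of quiet needs 8 frames
        times = np.arange(24) * 0.5
        counts = [1] * 4 + [0] * 7 + [1, 1] + [0] * 11
        call = call_death(times, counts)
        assert (call.status, call.time_h) == ("dead", times[12])

    def test_confirm_one_always_resets(self):
        counts = [1, 1, 1, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0]
        call = call_death(np.arange(13.0), counts, confirm_m=1)
        assert (call.status, call.time_h) == ("dead", 8.0)

    def test_excluded_and_empty_statuses(self):
        from wormarena.vitality import OccupancyClass

        occ4 = OccupancyClass("4+", 10.0, excluded=True)
        assert call_death(np.arange(9.0), [0] * 9, occupancy=occ4).status == "excluded"
        occ0 = OccupancyClass("0", 10.0, excluded=False)
        assert call_death(np.arange(9.0), [0] * 9, occupancy=occ0).status == "empty"

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        counts=st.lists(st.integers(0, 2), min_size=5, max_size=40),
        confirm_m=st.integers(1, 3),
    )
    def test_backward_pass_equals_forward_oracle(self, counts, confirm_m):
        times = np.arange(len(counts), dtype=float)
        call = call_death(times, counts, confirm_m=confirm_m)
        status, t = forward_death_oracle(times, counts, confirm_m=confirm_m)
        assert call.status == status
        assert call.time_h == t


class TestYieldAndBreakdown:
    def test_zero_and_full(self):
        assert compute_yield([], 50) == 0.0
        calls = [DeathCall(i, "dead", time_h=10.0) for i in range(50)]
        assert compute_yield(calls, 50) == 1.0

    def test_censored_counts_excluded_do_not(self):
        calls = [
            DeathCall(0, "dead", time_h=5.0),
            DeathCall(1, "censored", time_h=8.0),
            DeathCall(2, "excluded"),
            DeathCall(3, "empty"),
        ]
        assert compute_yield(calls, 4) == 0.5
        with pytest.raises(ValueError):
            compute_yield(calls, 0)

    def test_breakdown_percentages(self):
        labels = ["1"] * 3 + ["0"] * 2 + ["4+"]
        out = occupancy_breakdown(labels)
        assert out == {"0": 33.3, "1": 50.0, "4+": 16.7}


class TestMovementTable:
    def test_arena_order_permutation_invariant(self):
        rng = np.random.default_rng(3)
        times = np.arange(6.0)
        per_arena = []
        for a in range(5):
            pos = rng.uniform(30, 70, 2)
            frames = []
            for f in range(6):
                pos = pos + rng.normal(0, 6, 2)
                frames.append([obj(*pos, arena=a, t=float(f))])
            per_arena.append(frames)
        t1, _ = movement_table(per_arena, times)
        perm = [3, 1, 4, 0, 2]
        t2, _ = movement_table([per_arena[i] for i in perm], times)
        for new_idx, old_idx in enumerate(perm):
            np.testing.assert_array_equal(t2[new_idx].counts, t1[old_idx].counts)
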