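"""Frame alignment, optimal identity matching and event classification."""

import numpy as np
import pytest

import spinedyn as sd
from spinedyn import ProtrusionClass
from spinedyn.tracking import track_frame_pair

from conftest import make_frame


def brute_force_match(x1, x2, cap):
    """Exhaustive best assignment: max within-cap matches, then min cost.

    Bitmask recursion over frame-2 availability; independent of the
    rectangular-assignment solver used by the implementation.
    """
    n1, n2 = len(x1), len(x2)
    best = {}

    def rec(i, mask):
        if i == n1:
            return (0, 0.0)
        key = (i, mask)
        if key in best:
            return best[key]
        n_m, cost = rec(i + 1, mask)  # leave i unmatched
        res = (n_m, cost)
        for j in range(n2):
            if mask & (1 << j):
                continue
            d = abs(x1[i] - x2[j])
            if d <= cap:
                n_m, cost = rec(i + 1, mask | (1 << j))
                cand = (n_m + 1, cost + d)
                if cand[0] > res[0] or (cand[0] == res[0] and cand[1] < res[1]):
                    res = cand
        best[key] = res
        return res

    return rec(0, 0)


def test_alignment_recovers_exact_shift():
    f1 = make_frame([5.0, 12.0, 20.0, 33.0])
    f2 = make_frame([5.3, 12.3, 20.3, 33.3], timepoint_h=1.0)
    assert sd.align_frames(f1, f2) == pytest.approx(0.3)
    assert sd.align_frames(f1, f1) == pytest.approx(0.0)
    assert sd.align_frames(make_frame([]), f2) == 0.0


def test_alignment_small_under_jitter():
    """With only jitter (sd 0.15 μm), the estimated offset stays < 0.1 μm
    in at least 95% of simulated frame pairs."""
    params = sd.get_condition("cortex_4wk_control_1h", seed=21)
    small = 0
    n_rep = 200
    for i in range(n_rep):
        d = sd.simulate_dendrite(params, f"d{i:03d}")
        if abs(sd.align_frames(d.frame1, d.frame2)) < 0.1:
            small += 1
    assert small / n_rep >= 0.95


def test_identical_frames_fully_matched():
    f1 = make_frame([3.0, 10.0, 22.0])
    track = sd.match_protrusions(f1, f1)
    assert track.n_matched == 3
    assert track.formed_ids == [] and track.eliminated_ids == []


def test_threshold_rule_example():
    """Displacement 0.3 matches; 0.9 exceeds the 0.7 μm cap."""
    f1 = make_frame([10.0, 12.0])
    f2 = make_frame([10.3, 12.9], timepoint_h=1.0)
    track = sd.match_protrusions(f1, f2, align=False)
    assert [(a, b) for a, b, _ in track.matched_pairs] == [("p000", "p000")]
    assert track.matched_pairs[0][2] == pytest.approx(0.3)
    assert track.eliminated_ids == ["p001"]
    assert track.formed_ids == ["p001"]


def test_optimal_not_greedy():
    """{10.0, 10.6} -> {10.5, 11.2}: the min-total assignment keeps both
    matched (cost 1.1) instead of greedily pairing 10.6 with 10.5."""
    f1 = make_frame([10.0, 10.6])
    f2 = make_frame([10.5, 11.2], timepoint_h=1.0)
    track = sd.match_protrusions(f1, f2, align=False)
    pairs = {(a, b) for a, b, _ in track.matched_pairs}
    assert pairs == {("p000", "p000"), ("p001", "p001")}
    assert sum(d for _, _, d in track.matched_pairs) == pytest.approx(1.1)


@pytest.mark.parametrize("n_frames", [150])
def test_matching_equals_brute_force(n_frames, rng):
    """Assignment solver agrees with exhaustive search on small frames."""
    for _ in range(n_frames):
        n1, n2 = rng.integers(0, 9), rng.integers(0, 9)
        x1 = np.sort(rng.uniform(0, 4.0, n1))
        x2 = np.sort(rng.uniform(0, 4.0, n2))
        f1 = make_frame(x1)
        f2 = make_frame(x2, timepoint_h=1.0)
        track = sd.match_protrusions(f1, f2, align=False)
        bf_n, bf_cost = brute_force_match(list(x1), list(x2), 0.7)
        assert track.n_matched == bf_n
        assert sum(d for _, _, d in track.matched_pairs) == pytest.approx(
            bf_cost, abs=1e-7
        )


def test_symmetry_formed_eliminated(rng):
    for _ in range(30):
        x1 = np.sort(rng.uniform(0, 20.0, rng.integers(0, 12)))
        x2 = np.sort(rng.uniform(0, 20.0, rng.integers(0, 12)))
        f1 = make_frame(x1)
        f2 = make_frame(x2, timepoint_h=1.0)
        fwd = sd.match_protrusions(f1, f2, align=False)
        rev = sd.match_protrusions(f2, f1, align=False)
        assert len(fwd.formed_ids) == len(rev.eliminated_ids)
        assert len(fwd.eliminated_ids) == len(rev.formed_ids)


def test_cap_monotonicity(rng):
    """A larger cap never produces more formation+elimination events."""
    for _ in range(20):
        x1 = np.sort(rng.uniform(0, 20.0, rng.integers(1, 12)))
        x2 = np.sort(rng.uniform(0, 20.0, rng.integers(1, 12)))
        f1 = make_frame(x1)
        f2 = make_frame(x2, timepoint_h=1.0)
        events = []
        for cap in (0.3, 0.7, 1.5, 3.0):
            t = sd.match_protrusions(f1, f2, cap_um=cap, align=False)
            events.append(len(t.formed_ids) + len(t.eliminated_ids))
        assert all(a >= b for a, b in zip(events, events[1:]))


def test_no_displacement_exceeds_cap(rng):
    for _ in range(20):
        f1 = make_frame(np.sort(rng.uniform(0, 10.0, 8)))
        f2 = make_frame(np.sort(rng.uniform(0, 10.0, 8)), timepoint_h=1.0)
        t = sd.match_protrusions(f1, f2, align=False)
        assert all(d <= 0.7 + 1e-12 for _, _, d in t.matched_pairs)


def test_event_counts_simple():
    """20 spines, 2 eliminated, 2 formed -> (18, 2, 2)."""
    x1 = np.linspace(1, 39, 20)
    x2 = np.concatenate([x1[:-2], [8.5, 23.5]])  # drop last two, add two
    f1 = make_frame(x1)
    f2 = make_frame(np.sort(x2), timepoint_h=1.0)
    classes1 = sd.classify_frame(f1)
    classes2 = sd.classify_frame(f2)
    track = sd.match_protrusions(f1, f2, align=False)
    ev = sd.classify_events(track, classes1, classes2)
    assert ev["spine"] == {"persisting": 18, "formed": 2, "eliminated": 2}
    assert ev["all"] == {"persisting": 18, "formed": 2, "eliminated": 2}


def test_class_transition_conventions():
    """A matched protrusion changing filopodium->spine is an elimination in
    the old class and a formation in the new class by default, but counts
    as persisting under the persistence convention."""
    f1 = make_frame([10.0], filo_flags=[True])
    f2 = make_frame([10.1], timepoint_h=1.0)  # spine-like morphometry
    classes1 = sd.classify_frame(f1)
    classes2 = sd.classify_frame(f2)
    assert classes1["p000"] is ProtrusionClass.FILOPODIUM
    assert classes2["p000"] is ProtrusionClass.SPINE
    track = sd.match_protrusions(f1, f2, align=False)
    ev = sd.classify_events(track, classes1, classes2, "within_class")
    assert ev["filopodium"]["eliminated"] == 1
    assert ev["spine"]["formed"] == 1
    assert ev["all"] == {"persisting": 1, "formed": 0, "eliminated": 0}
    ev2 = sd.classify_events(track, classes1, classes2, "persistence")
    assert ev2["filopodium"] == {"persisting": 1, "formed": 0, "eliminated": 0}


def test_ground_truth_recovered_without_events():
    """Zero jitter and no birth/death: tracking recovers the ground-truth
    correspondence exactly; with default jitter the event counts stay 0."""
    params = sd.get_condition(
        "cortex_4wk_control_1h",
        seed=5,
        jitter_sd_um=0.0,
        spine_formation_prob=0.0,
        spine_elimination_prob=0.0,
        filo_formation_prob=0.0,
        filo_elimination_prob=0.0,
    )
    for i in range(20):
        d = sd.simulate_dendrite(params, f"d{i:02d}")
        track = sd.match_protrusions(d.frame1, d.frame2)
        assert {(a, b) for a, b, _ in track.matched_pairs} == set(
            d.ground_truth.correspondence.items()
        )
        assert track.formed_ids == [] and track.eliminated_ids == []


def test_track_frame_pair_by_class_counts():
    """Class-scoped matching never pairs a spine with a filopodium."""
    f1 = make_frame([10.0, 10.2], filo_flags=[True, False])
    f2 = make_frame([10.05, 10.25], timepoint_h=1.0, filo_flags=[False, True])
    classes1 = sd.classify_frame(f1)
    classes2 = sd.classify_frame(f2)
    ev, tracks = track_frame_pair(f1, f2, classes1, classes2)
    # the filopodium at 10.0 matches the filopodium at 10.25, the spine at
    # 10.2 matches the spine at 10.05: identity follows morphology
    assert ev["spine"] == {"persisting": 1, "formed": 0, "eliminated": 0}
    assert ev["filopodium"] == {"persisting": 1, "formed": 0, "eliminated": 0}
    assert ev["all"]["persisting"] == 2
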