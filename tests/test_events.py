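import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glycoadhesion.contacts import ContactSeries
from glycoadhesion.errors import UndefinedEstimateError, UsageError
from glycoadhesion.events import (
    binding_probability,
    classify_binding,
    discard_burn_in,
    effective_trans_constant,
    estimate_pair_binding,
    pair_binding_constant,
    segment_events,
    sem_over_trajectories,
    trans_engagement,
)
from glycoadhesion.synthetic import KineticParams, simulate_binding_kinetics
from glycoadhesion.trajectory import PairSpec

from conftest import series_pair


def make_series(counts, interval=0.1, pair=None):
    return ContactSeries(pair or series_pair(), np.asarray(counts), interval)


def rle_oracle(counts):
    """Independent run-length encoding of nonzero stretches."""
    runs, start = [], None
    for i, c in enumerate(counts):
        if c > 0 and start is None:
            start = i
        elif c == 0 and start is not None:
            runs.append((start, i - 1, max(counts[start:i])))
            start = None
    if start is not None:
        runs.append((start, len(counts) - 1, max(counts[start:])))
    return runs


def test_all_zero_series_has_no_events():
    assert segment_events(make_series([0, 0, 0])) == []
    assert segment_events(make_series([])) == []


def test_two_event_example():
    """(0,2,3,0,0,7,1,0) at 0.1 ns → events 1–2 (max 3) and 5–6 (max 7)."""
    events = segment_events(make_series([0, 2, 3, 0, 0, 7, 1, 0]))
    assert [(e.start_frame, e.end_frame, e.max_contacts) for e in events] == [
        (1, 2, 3),
        (5, 6, 7),
    ]
    assert all(e.lifetime == pytest.approx(0.2) for e in events)


def test_run_touching_both_boundaries():
    (event,) = segment_events(make_series([4, 4]))
    assert (event.start_frame, event.end_frame, event.max_contacts) == (0, 1, 4)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(counts=st.lists(st.integers(0, 12), max_size=60))
def test_segmentation_matches_rle_oracle(counts):
    events = segment_events(make_series(counts))
    assert [(e.start_frame, e.end_frame, e.max_contacts) for e in events] == rle_oracle(
        counts
    )
    # every nonzero frame belongs to exactly one event
    covered = [f for e in events for f in range(e.start_frame, e.end_frame + 1)]
    assert sorted(covered) == [i for i, c in enumerate(counts) if c > 0]
    assert len(set(covered)) == len(covered)


def test_classification_cutoff():
    events = segment_events(make_series([0, 2, 3, 0, 0, 7, 1, 0]))
    kept = classify_binding(events, n_c=5)
    assert [e.max_contacts for e in kept] == [7]
    assert classify_binding(events, n_c=1) == events


def test_retained_events_non_increasing_in_nc(rng):
    series, _ = simulate_binding_kinetics(n_frames=3000, seed=7)
    events = segment_events(series[0])
    sizes = [len(classify_binding(events, n_c=n)) for n in range(1, 16)]
    assert all(a >= b for a, b in zip(sizes, sizes[1:]))


def test_binding_probability_direct_count():
    assert binding_probability(make_series([0] * 10), burn_in_fraction=0.0) == 0.0
    counts = [0, 0, 0, 0, 0, 6, 6, 6, 6, 6]
    assert binding_probability(make_series(counts), burn_in_fraction=0.0) == 0.5


def test_burn_in_truncates_straddling_events():
    """Discarding happens before segmentation: an event crossing the cut is
    truncated at the cut and the retained part still counts."""
    counts = [7] * 4 + [0] * 4 + [7, 7]
    p = binding_probability(make_series(counts), burn_in_fraction=0.2)
    # 8 retained frames: frames 2,3 (truncated event) and 8,9 bound
    assert p == pytest.approx(0.5)


def test_subthreshold_frames_inside_binding_events_count_as_bound():
    counts = [0, 1, 9, 1, 0, 0]
    p = binding_probability(make_series(counts), n_c=5, burn_in_fraction=0.0)
    assert p == pytest.approx(3 / 6)


def test_burn_in_bounds():
    with pytest.raises(UsageError):
        discard_burn_in(make_series([1, 2]), 1.0)
    with pytest.raises(UndefinedEstimateError):
        discard_burn_in(make_series([1, 2]), 0.99)


def test_frame_conservation(rng):
    """bound + sub-threshold + zero frames = retained frames."""
    series, _ = simulate_binding_kinetics(n_frames=4000, seed=3)
    retained = discard_burn_in(series[0], 0.1)
    events = segment_events(retained)
    binding = classify_binding(events, 5)
    sub = [e for e in events if e.max_contacts < 5]
    n_bound = sum(e.n_frames for e in binding)
    n_sub = sum(e.n_frames for e in sub)
    n_zero = int(np.count_nonzero(retained.counts == 0))
    assert n_bound + n_sub + n_zero == len(retained.counts)


def test_pair_binding_constant_formula():
    assert pair_binding_constant(0.0, 23.3) == 0.0
    assert pair_binding_constant(0.5, 23.3) == pytest.approx(23.3)
    with pytest.raises(UndefinedEstimateError):
        pair_binding_constant(1.0, 23.3)


def test_effective_trans_constant_formula():
    assert effective_trans_constant(0.0, 10, 63.5) == 0.0
    assert effective_trans_constant(4.0, 10, 63.5) == pytest.approx(63.5 * 4 / 36)
    with pytest.raises(UndefinedEstimateError):
        effective_trans_constant(10.0, 10, 63.5)


def test_sem_closed_forms(rng):
    assert sem_over_trajectories([2.0, 2.0, 2.0]) == 0.0
    assert sem_over_trajectories([1.0, 3.0]) == pytest.approx(1.0)
    vals = rng.random(10)
    expected = np.std(vals, ddof=1) / np.sqrt(10)
    assert sem_over_trajectories(vals) == pytest.approx(expected)
    with pytest.raises(UndefinedEstimateError):
        sem_over_trajectories([1.0])


def _engagement_setup():
    """3 glycolipids in leaflet L bound to partners across; gA binds two."""
    pa1 = PairSpec("pa1", "gA", "hX", "trans")
    pa2 = PairSpec("pa2", "gA", "hY", "trans")
    pb = PairSpec("pb", "gB", "hX", "trans")
    series = [
        ContactSeries(pa1, [6, 6, 0, 0], 0.1),
        ContactSeries(pa2, [6, 0, 0, 0], 0.1),
        ContactSeries(pb, [0, 0, 6, 0], 0.1),
    ]
    events = {s.pair.pair_id: classify_binding(segment_events(s), 5) for s in series}
    return series, events


def test_engagement_counts_distinct_molecules():
    series, events = _engagement_setup()
    eng = trans_engagement(series, events, leaflet_molecules={"gA", "gB", "gC"})
    # frame 0: gA doubly bound still counts once
    assert list(eng.n_trans) == [1, 1, 1, 0]
    assert eng.mean == pytest.approx(0.75)


def test_engagement_bond_counting_mode():
    series, events = _engagement_setup()
    eng = trans_engagement(
        series, events, leaflet_molecules={"gA", "gB", "gC"}, count_bonds=True
    )
    assert list(eng.n_trans) == [2, 1, 1, 0]


def test_engagement_set_union_oracle(rng):
    """Random multi-pair series equal a brute-force per-frame set union."""
    mols = [f"g{i}" for i in range(4)]
    partners = [f"h{i}" for i in range(4)]
    series = []
    for i, a in enumerate(mols):
        for j, b in enumerate(partners):
            counts = rng.integers(0, 8, size=30) * (rng.random(30) < 0.3)
            series.append(ContactSeries(PairSpec(f"{a}-{b}", a, b, "trans"), counts, 0.1))
    events = {s.pair.pair_id: classify_binding(segment_events(s), 5) for s in series}
    eng = trans_engagement(series, events, leaflet_molecules=set(mols))
    for f in range(30):
        expected = {
            s.pair.molecule_a
            for s in series
            if any(e.covers(f) for e in events[s.pair.pair_id])
        }
        assert eng.n_trans[f] == len(expected)


def test_no_events_means_zero_engagement():
    series = [ContactSeries(series_pair(), [0, 0, 0], 0.1)]
    eng = trans_engagement(series, {}, leaflet_molecules={"gA"})
    assert not eng.n_trans.any()


def test_kinetic_recovery_within_3_sem():
    """Two-state synthetic chains recover planted P_b and K within 3 SEM."""
    params = KineticParams(k_on=0.5, k_off=1.0)  # P_b = 1/3
    per_seed = []
    for seed in range(10):
        series, truth = simulate_binding_kinetics(params, n_frames=10_000, seed=seed)
        est = estimate_pair_binding(series, area=params.area)
        per_seed.append(est.K)
    sem = sem_over_trajectories(per_seed)
    K_true = params.area * truth.P_b / (1 - truth.P_b)
    assert abs(np.mean(per_seed) - K_true) < 3 * sem


def test_K_non_increasing_in_nc():
    series, _ = simulate_binding_kinetics(n_frames=8000, seed=11)
    Ks = [
        pair_binding_constant(
            binding_probability(series[0], n_c=n, burn_in_fraction=0.1), 23.3
        )
        for n in range(1, 16)
    ]
    assert all(a >= b for a, b in zip(Ks, Ks[1:]))
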