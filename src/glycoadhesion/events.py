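"""Interaction-event segmentation and 2D binding-constant estimation.

An interaction event is a maximal run of consecutive frames with nonzero
tip–tip contacts. Events whose maximum contact count reaches the cutoff
``n_c`` (default 5) are binding events; shallower runs are collisions.
Because carbohydrate–carbohydrate binding is fuzzy — many interconverting
bound conformations rather than one complex — the distinction depends
mildly on ``n_c``; ``n_c = 10`` is offered as a sensitivity setting.

The bound-frame fraction P_b of the retained window (after burn-in) gives
the two-dimensional binding constant

    K = A * P_b / (1 - P_b)        [nm^2]

with A the membrane area. For membranes with N_g glycolipids per monolayer
that can engage several partners, the effective trans constant is the
mass-action estimator

    K_trans = A * n_trans / (N_g - n_trans)^2

with n_trans the mean number of glycolipids per monolayer engaged in at
least one trans binding event. Errors are SEMs over independent
trajectories.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

from .contacts import ContactSeries
from .errors import StructuralError, UndefinedEstimateError, UsageError
from .trajectory import PairSpec

__all__ = [
    "InteractionEvent",
    "BindingEstimate",
    "TransEngagement",
    "segment_events",
    "classify_binding",
    "discard_burn_in",
    "binding_probability",
    "pair_binding_constant",
    "trans_engagement",
    "effective_trans_constant",
    "sem_over_trajectories",
    "estimate_pair_binding",
    "write_event_table",
]

DEFAULT_N_C = 5
DEFAULT_BURN_IN_TRANS = 0.10
DEFAULT_BURN_IN_CIS = 0.20


@dataclass(frozen=True)
class InteractionEvent:
    """Maximal nonzero-contact run: inclusive frame span, lifetime, depth."""

    pair: PairSpec
    start_frame: int
    end_frame: int
    lifetime: float  # ns
    max_contacts: int

    def __post_init__(self) -> None:
        if self.start_frame > self.end_frame:
            raise StructuralError("event start after end")
        if self.max_contacts < 1:
            raise StructuralError("an event needs at least one contact")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1

    def covers(self, frame: int) -> bool:
        return self.start_frame <= frame <= self.end_frame


@dataclass
class BindingEstimate:
    """P_b and K with SEM over trajectories; `sem_K` is NaN when undefined."""

    P_b: float
    K: float
    sem_K: float
    n_events: int
    n_c: int
    burn_in_fraction: float
    area: float
    per_trajectory_K: list[float] = field(default_factory=list)
    per_trajectory_P_b: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "P_b": self.P_b,
            "K_nm2": self.K,
            "sem_K_nm2": None if math.isnan(self.sem_K) else self.sem_K,
            "n_events": self.n_events,
            "n_c": self.n_c,
            "burn_in_fraction": self.burn_in_fraction,
            "area_nm2": self.area,
            "per_trajectory_K_nm2": self.per_trajectory_K,
            "per_trajectory_P_b": self.per_trajectory_P_b,
        }


@dataclass
class TransEngagement:
    """Per-frame count of distinct glycolipids in one leaflet with >=1 trans bond."""

    n_trans: np.ndarray
    N_g: int

    def __post_init__(self) -> None:
        self.n_trans = np.asarray(self.n_trans, dtype=int)
        if np.any(self.n_trans < 0) or np.any(self.n_trans > self.N_g):
            raise StructuralError("n_trans out of [0, N_g]")

    @property
    def mean(self) -> float:
        return float(np.mean(self.n_trans)) if self.n_trans.size else 0.0


def segment_events(series: ContactSeries) -> list[InteractionEvent]:
    """Maximal runs of nonzero contact counts, in frame order.

    Runs touching the series boundaries count as events; every nonzero
    frame belongs to exactly one event.
    """
    counts = series.counts
    if counts.size == 0:
        return []
    nz = counts > 0
    padded = np.concatenate([[False], nz, [False]])
    d = np.diff(padded.astype(int))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0] - 1
    return [
        InteractionEvent(
            pair=series.pair,
            start_frame=int(s),
            end_frame=int(e),
            lifetime=(int(e) - int(s) + 1) * series.frame_interval,
            max_contacts=int(counts[s : e + 1].max()),
        )
        for s, e in zip(starts, ends)
    ]


def classify_binding(
    events: list[InteractionEvent], n_c: int = DEFAULT_N_C
) -> list[InteractionEvent]:
    """Keep events with max_contacts >= n_c (order preserved)."""
    if n_c < 1:
        raise UsageError("n_c must be >= 1")
    return [e for e in events if e.max_contacts >= n_c]


def discard_burn_in(series: ContactSeries, burn_in_fraction: float) -> ContactSeries:
    """Drop the first ceil(fraction * n) frames; events straddling the cut
    are truncated at the cut (segmentation happens on the retained window)."""
    if not 0 <= burn_in_fraction < 1:
        raise UsageError("burn_in_fraction must be in [0, 1)")
    n = len(series.counts)
    n_discard = math.ceil(burn_in_fraction * n)
    if n_discard >= n:
        raise UndefinedEstimateError("burn-in discards every frame")
    return ContactSeries(
        pair=series.pair,
        counts=series.counts[n_discard:],
        frame_interval=series.frame_interval,
        cutoff=series.cutoff,
    )


def binding_probability(
    series: ContactSeries,
    n_c: int = DEFAULT_N_C,
    burn_in_fraction: float = DEFAULT_BURN_IN_TRANS,
) -> float:
    """Fraction of retained frames inside binding events.

    All frames of a binding event count as bound, including frames whose
    instantaneous contact count lies below n_c.
    """
    retained = discard_burn_in(series, burn_in_fraction)
    if len(retained.counts) == 0:
        raise UndefinedEstimateError("no frames retained after burn-in")
    events = classify_binding(segment_events(retained), n_c)
    bound = sum(e.n_frames for e in events)
    return bound / len(retained.counts)


def pair_binding_constant(P_b: float, area: float) -> float:
    """K = A * P_b / (1 - P_b), in nm^2."""
    if not 0 <= P_b < 1:
        raise UndefinedEstimateError(f"P_b must be in [0, 1), got {P_b}")
    if area <= 0:
        raise UsageError("membrane area must be positive")
    return area * P_b / (1.0 - P_b)


def trans_engagement(
    series_by_pair: list[ContactSeries],
    binding_events: dict[str, list[InteractionEvent]],
    leaflet_molecules: set[str],
    N_g: int | None = None,
    count_bonds: bool = False,
) -> TransEngagement:
    """Per-frame number of distinct engaged glycolipids in one leaflet.

    A glycolipid is engaged at a frame iff at least one of its trans pairs
    is inside a binding event covering that frame. ``count_bonds=True``
    switches to counting bonds (binding events active at the frame whose
    pair touches the leaflet) instead of distinct molecules.
    """
    lengths = {len(s.counts) for s in series_by_pair}
    if len(lengths) > 1:
        raise StructuralError(f"contact series disagree on frame count: {sorted(lengths)}")
    n_frames = lengths.pop() if lengths else 0
    if N_g is None:
        N_g = len(leaflet_molecules)
    bond_count = np.zeros(n_frames, dtype=int)
    engaged = [set() for _ in range(n_frames)]
    for s in series_by_pair:
        if s.pair.relation != "trans":
            continue
        members = {s.pair.molecule_a, s.pair.molecule_b} & leaflet_molecules
        if not members:
            continue
        for ev in binding_events.get(s.pair.pair_id, []):
            for f in range(ev.start_frame, ev.end_frame + 1):
                bond_count[f] += 1
                engaged[f].update(members)
    if count_bonds:
        return TransEngagement(n_trans=bond_count, N_g=max(N_g, int(bond_count.max(initial=0))))
    return TransEngagement(n_trans=np.array([len(s) for s in engaged]), N_g=N_g)


def effective_trans_constant(mean_n_trans: float, N_g: int, area: float) -> float:
    """Mass-action estimator K = A * n_trans / (N_g - n_trans)^2."""
    if not 0 <= mean_n_trans < N_g:
        raise UndefinedEstimateError(
            f"mean_n_trans must be in [0, N_g={N_g}), got {mean_n_trans}"
        )
    if area <= 0:
        raise UsageError("membrane area must be positive")
    return area * mean_n_trans / (N_g - mean_n_trans) ** 2


def sem_over_trajectories(values) -> float:
    """Standard error of the mean over independent trajectories."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise UndefinedEstimateError(
            "SEM needs values from at least 2 independent trajectories"
        )
    return float(np.std(values, ddof=1) / np.sqrt(values.size))


def estimate_pair_binding(
    series_per_trajectory: list[ContactSeries],
    area: float,
    n_c: int = DEFAULT_N_C,
    burn_in_fraction: float = DEFAULT_BURN_IN_TRANS,
) -> BindingEstimate:
    """Pool one glycolipid pair's series over independent trajectories.

    P_b pools bound/retained frames over all trajectories; K is derived
    from the pooled P_b, and sem_K is the SEM of per-trajectory K values
    (NaN if fewer than two trajectories).
    """
    if not series_per_trajectory:
        raise UndefinedEstimateError("no contact series supplied")
    bound_total = retained_total = n_events = 0
    per_K, per_P = [], []
    for series in series_per_trajectory:
        retained = discard_burn_in(series, burn_in_fraction)
        events = classify_binding(segment_events(retained), n_c)
        bound = sum(e.n_frames for e in events)
        p = bound / len(retained.counts)
        per_P.append(p)
        per_K.append(pair_binding_constant(p, area) if p < 1 else math.inf)
        bound_total += bound
        retained_total += len(retained.counts)
        n_events += len(events)
    P_b = bound_total / retained_total
    sem_K = (
        sem_over_trajectories(per_K) if len(per_K) >= 2 and all(map(math.isfinite, per_K))
        else math.nan
    )
    return BindingEstimate(
        P_b=P_b,
        K=pair_binding_constant(P_b, area),
        sem_K=sem_K,
        n_events=n_events,
        n_c=n_c,
        burn_in_fraction=burn_in_fraction,
        area=area,
        per_trajectory_K=per_K,
        per_trajectory_P_b=per_P,
    )


def write_event_table(
    events: list[InteractionEvent],
    binding: set | None,
    path: str | os.PathLike,
) -> None:
    """Write `pair_id relation start end lifetime_ns max_contacts is_binding`."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# pair_id relation start_frame end_frame lifetime_ns max_contacts is_binding\n")
        for ev in events:
            flag = int(binding is None or ev in binding)
            fh.write(
                f"{ev.pair.pair_id} {ev.pair.relation} {ev.start_frame} "
                f"{ev.end_frame} {ev.lifetime:.6g} {ev.max_contacts} {flag}\n"
            )


def write_estimate_report(estimate: BindingEstimate, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(estimate.to_dict(), fh, indent=1)
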