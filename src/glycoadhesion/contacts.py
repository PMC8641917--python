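"""Heavy-atom contact counting between carbohydrate tips under PBC.

A contact is a pair of tip heavy atoms, one from each glycolipid, at a
minimum-image distance strictly below the cutoff (default 0.45 nm). The
minimum image is taken over all three axes — including z, because trans
partners in single-membrane systems interact across the periodic z
boundary. Boxes may vary per frame (semi-isotropic barostat).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from .errors import MalformedInputError, NumericError, UsageError
from .trajectory import BoxedFrame, MoleculeSelection, PairSpec, Trajectory

__all__ = [
    "ContactSeries",
    "minimum_image_distance",
    "count_tip_contacts",
    "count_all_tip_contacts",
    "build_contact_series",
    "write_contact_series",
    "read_contact_series",
]

DEFAULT_CUTOFF = 0.45  # nm


@dataclass
class ContactSeries:
    """Per-frame tip–tip contact counts for one glycolipid pair."""

    pair: PairSpec
    counts: np.ndarray
    frame_interval: float
    cutoff: float = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if np.any(self.counts < 0):
            raise UsageError("contact counts must be non-negative")
        if self.cutoff <= 0:
            raise UsageError("cutoff must be positive")
        if self.frame_interval <= 0:
            raise UsageError("frame_interval must be positive")

    def __len__(self) -> int:
        return len(self.counts)


def minimum_image_distance(p, q, box) -> float | np.ndarray:
    """Smallest |p - q + n*box| over integer image shifts n, per axis.

    For orthorhombic boxes, rounding each component displacement to its
    nearest image is exact. Accepts broadcastable arrays; the distance is
    computed over the last axis.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    box = np.asarray(box, dtype=float)
    if np.any(box <= 0):
        raise UsageError(f"box edges must be positive, got {box}")
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(q))):
        raise NumericError("non-finite coordinates in distance calculation")
    delta = p - q
    delta -= box * np.round(delta / box)
    return np.sqrt(np.sum(delta * delta, axis=-1))


def count_tip_contacts(
    frame: BoxedFrame,
    a: MoleculeSelection,
    b: MoleculeSelection,
    cutoff: float = DEFAULT_CUTOFF,
) -> int:
    """Number of tip heavy-atom pairs closer than ``cutoff`` (strict <)."""
    if a.molecule_id == b.molecule_id:
        raise UsageError("cannot count contacts of a molecule with itself")
    if a.tip_heavy_atoms.size == 0 or b.tip_heavy_atoms.size == 0:
        raise UsageError("both molecules need nonempty tip_heavy_atoms")
    pa = frame.coordinates[a.tip_heavy_atoms]
    pb = frame.coordinates[b.tip_heavy_atoms]
    d = minimum_image_distance(pa[:, None, :], pb[None, :, :], frame.box)
    return int(np.count_nonzero(d < cutoff))


def count_all_tip_contacts(
    frame: BoxedFrame,
    group_a: list[MoleculeSelection],
    group_b: list[MoleculeSelection],
    cutoff: float = DEFAULT_CUTOFF,
) -> np.ndarray:
    """Contact counts for every (a, b) molecule pair in one pass.

    Returns an integer matrix of shape (len(group_a), len(group_b)).
    Equivalent to calling :func:`count_tip_contacts` per pair, but with one
    vectorized distance evaluation — the per-pair route is the oracle.
    """
    atoms_a = np.concatenate([m.tip_heavy_atoms for m in group_a])
    atoms_b = np.concatenate([m.tip_heavy_atoms for m in group_b])
    label_a = np.concatenate(
        [np.full(m.tip_heavy_atoms.size, i) for i, m in enumerate(group_a)]
    )
    label_b = np.concatenate(
        [np.full(m.tip_heavy_atoms.size, j) for j, m in enumerate(group_b)]
    )
    pa = frame.coordinates[atoms_a]
    pb = frame.coordinates[atoms_b]
    d = minimum_image_distance(pa[:, None, :], pb[None, :, :], frame.box)
    hit = d < cutoff
    counts = np.zeros((len(group_a), len(group_b)), dtype=int)
    if hit.any():
        ia, ib = np.nonzero(hit)
        np.add.at(counts, (label_a[ia], label_b[ib]), 1)
    return counts


def build_contact_series(
    traj: Trajectory,
    pairs: list[PairSpec],
    selections: dict[str, MoleculeSelection] | list[MoleculeSelection],
    cutoff: float = DEFAULT_CUTOFF,
    analysis_interval: float | None = None,
) -> list[ContactSeries]:
    """Per-pair contact time series on the analysis frame grid.

    If the trajectory is saved more finely than ``analysis_interval``, frames
    are taken at an integer stride; a non-integer ratio is an error.
    """
    if isinstance(selections, list):
        selections = {s.molecule_id: s for s in selections}
    if analysis_interval is None:
        analysis_interval = traj.frame_interval
    ratio = analysis_interval / traj.frame_interval
    stride = int(round(ratio))
    if stride < 1 or abs(ratio - stride) > 1e-6 * ratio:
        raise UsageError(
            f"analysis interval {analysis_interval:g} ns is not an integer "
            f"multiple of the trajectory interval {traj.frame_interval:g} ns"
        )
    frames = traj.frames[::stride]
    counts = np.zeros((len(pairs), len(frames)), dtype=int)
    for fi, frame in enumerate(frames):
        for pi, pair in enumerate(pairs):
            counts[pi, fi] = count_tip_contacts(
                frame, selections[pair.molecule_a], selections[pair.molecule_b], cutoff
            )
    return [
        ContactSeries(
            pair=pair,
            counts=counts[pi],
            frame_interval=analysis_interval,
            cutoff=cutoff,
        )
        for pi, pair in enumerate(pairs)
    ]


# ---------------------------------------------------------------------------
# export: text table plus JSON sidecar with provenance
# ---------------------------------------------------------------------------


def write_contact_series(
    series_list: list[ContactSeries], path: str | os.PathLike, provenance: dict | None = None
) -> None:
    """Write ``pair_id frame_index count`` rows plus a ``.json`` sidecar."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# pair_id frame_index count\n")
        for s in series_list:
            for fi, c in enumerate(s.counts):
                fh.write(f"{s.pair.pair_id} {fi} {c}\n")
    sidecar = {
        "cutoff_nm": series_list[0].cutoff if series_list else DEFAULT_CUTOFF,
        "frame_interval_ns": series_list[0].frame_interval if series_list else None,
        "pairs": {
            s.pair.pair_id: {
                "molecule_a": s.pair.molecule_a,
                "molecule_b": s.pair.molecule_b,
                "relation": s.pair.relation,
            }
            for s in series_list
        },
        "provenance": provenance or {},
    }
    with open(str(path) + ".json", "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=1)


def read_contact_series(path: str | os.PathLike) -> list[ContactSeries]:
    with open(str(path) + ".json", "r", encoding="utf-8") as fh:
        sidecar = json.load(fh)
    per_pair: dict[str, dict[int, int]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            pid, fi, c = line.split()
            per_pair.setdefault(pid, {})[int(fi)] = int(c)
    out = []
    for pid, meta in sidecar["pairs"].items():
        frames = per_pair.get(pid, {})
        if frames and sorted(frames) != list(range(len(frames))):
            raise MalformedInputError(f"{path}: non-consecutive frames for pair {pid}")
        counts = np.array([frames[i] for i in range(len(frames))], dtype=int)
        out.append(
            ContactSeries(
                pair=PairSpec(pid, meta["molecule_a"], meta["molecule_b"], meta["relation"]),
                counts=counts,
                frame_interval=sidecar["frame_interval_ns"],
                cutoff=sidecar["cutoff_nm"],
            )
        )
    return out
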