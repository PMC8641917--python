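"""Trajectory data model, canonical text I/O, and molecule bookkeeping.

Internal units are fixed: lengths in nm, times in ns, angles in degrees.
Boxes are orthorhombic; triclinic input is rejected. Leaflet membership is
taken from the topology table and never inferred from coordinates, because
z-based leaflet inference is fragile when membranes fluctuate strongly.

Canonical coordinate-table format (UTF-8, whitespace separated)::

    #interval 0.1
    #box 5.0 5.0 5.5          # one line for a constant box, or one per frame
    0 0 1.25 0.30 2.10        # frame_index particle_index x y z   (nm)
    0 1 ...

Topology table rows: ``particle_index molecule_id kind leaflet role mass``
with kind in {glycolipid, lipid}, leaflet like ``m1_upper`` (membrane 1,
upper monolayer; bare ``upper``/``lower`` normalize to membrane 1), and
role in {tip, tail, other}.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .errors import MalformedInputError, StructuralError, UsageError

__all__ = [
    "BoxedFrame",
    "Trajectory",
    "MoleculeSelection",
    "PairSpec",
    "read_trajectory",
    "write_trajectory",
    "read_topology",
    "build_selections",
    "infer_relation",
    "make_pair",
]

_REL_TOL = 1e-6  # relative tolerance on frame spacing

_KINDS = {"glycolipid", "lipid"}
_ROLES = {"tip", "tail", "other"}


@dataclass
class BoxedFrame:
    """One trajectory frame: time (ns), (N, 3) coordinates (nm), box edges (nm)."""

    time: float
    coordinates: np.ndarray
    box: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise StructuralError(
                f"coordinates must be (N, 3), got shape {self.coordinates.shape}"
            )
        if self.box.shape != (3,):
            raise StructuralError("box must be three orthorhombic edge lengths")
        if not np.all(self.box > 0):
            raise StructuralError(f"box edges must be positive, got {self.box}")

    @property
    def n_particles(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class Trajectory:
    """Time-ordered frames with a fixed saving interval (ns)."""

    frames: list[BoxedFrame]
    frame_interval: float
    trajectory_id: str = "traj"

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise StructuralError("frame_interval must be positive")
        n_particles = {f.n_particles for f in self.frames}
        if len(n_particles) > 1:
            raise StructuralError(
                f"frames disagree on particle count: {sorted(n_particles)}"
            )
        times = np.array([f.time for f in self.frames])
        if len(times) > 1:
            dt = np.diff(times)
            if np.any(dt <= 0):
                i = int(np.argmax(dt <= 0))
                raise MalformedInputError(
                    f"frame times not strictly increasing at frame {i + 1} "
                    f"(t={times[i + 1]:g} after t={times[i]:g})"
                )
            bad = np.abs(dt - self.frame_interval) > _REL_TOL * self.frame_interval
            if np.any(bad):
                i = int(np.argmax(bad))
                raise MalformedInputError(
                    f"frame spacing {dt[i]:g} ns between frames {i} and {i + 1} "
                    f"does not match declared interval {self.frame_interval:g} ns"
                )

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i: int) -> BoxedFrame:
        return self.frames[i]

    @property
    def n_particles(self) -> int:
        return self.frames[0].n_particles if self.frames else 0

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])


@dataclass
class MoleculeSelection:
    """Per-molecule particle bookkeeping.

    ``membrane`` is 1 or 2 and ``leaflet`` is "upper"/"lower"; glycolipids
    carry a nonempty set of tip heavy atoms, plain lipids none. Tail atoms
    carry per-atom masses for center-of-mass work.
    """

    molecule_id: str
    kind: str
    membrane: int
    leaflet: str
    tip_heavy_atoms: np.ndarray
    tail_atoms: np.ndarray
    tail_masses: np.ndarray
    other_atoms: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __post_init__(self) -> None:
        self.tip_heavy_atoms = np.asarray(self.tip_heavy_atoms, dtype=int)
        self.tail_atoms = np.asarray(self.tail_atoms, dtype=int)
        self.tail_masses = np.asarray(self.tail_masses, dtype=float)
        self.other_atoms = np.asarray(self.other_atoms, dtype=int)
        if self.kind not in _KINDS:
            raise StructuralError(f"unknown molecule kind {self.kind!r}")
        if self.kind == "glycolipid" and self.tip_heavy_atoms.size == 0:
            raise StructuralError(
                f"glycolipid {self.molecule_id!r} has no tip heavy atoms"
            )
        if self.kind == "lipid" and self.tip_heavy_atoms.size > 0:
            raise StructuralError(f"plain lipid {self.molecule_id!r} has tip atoms")
        if self.tail_masses.shape != self.tail_atoms.shape:
            raise StructuralError("tail_masses must align with tail_atoms")
        sets = [set(self.tip_heavy_atoms), set(self.tail_atoms), set(self.other_atoms)]
        if sum(len(s) for s in sets) != len(set().union(*sets)):
            raise StructuralError(
                f"tip/tail/other index sets of {self.molecule_id!r} overlap"
            )

    @property
    def all_atoms(self) -> np.ndarray:
        return np.concatenate(
            [self.tip_heavy_atoms, self.tail_atoms, self.other_atoms]
        )

    @property
    def leaflet_key(self) -> tuple[int, str]:
        return (self.membrane, self.leaflet)


@dataclass(frozen=True)
class PairSpec:
    """A glycolipid pair with its trans/cis relation."""

    pair_id: str
    molecule_a: str
    molecule_b: str
    relation: str  # "trans" or "cis"

    def __post_init__(self) -> None:
        if self.relation not in ("trans", "cis"):
            raise UsageError(f"relation must be 'trans' or 'cis', got {self.relation!r}")
        if self.molecule_a == self.molecule_b:
            raise UsageError("a pair needs two distinct molecules")


def infer_relation(a: MoleculeSelection, b: MoleculeSelection) -> str:
    """cis iff the two molecules share membrane and leaflet, else trans.

    Trans partners sit in apposing leaflets; in single-membrane systems the
    two monolayers interact across the periodic z-boundary, so any two
    distinct leaflets qualify as trans.
    """
    return "cis" if a.leaflet_key == b.leaflet_key else "trans"


def make_pair(a: MoleculeSelection, b: MoleculeSelection, pair_id: str | None = None) -> PairSpec:
    if a.molecule_id == b.molecule_id:
        raise UsageError("a pair needs two distinct molecules")
    return PairSpec(
        pair_id=pair_id or f"{a.molecule_id}-{b.molecule_id}",
        molecule_a=a.molecule_id,
        molecule_b=b.molecule_id,
        relation=infer_relation(a, b),
    )


# ---------------------------------------------------------------------------
# canonical coordinate-table I/O
# ---------------------------------------------------------------------------

_COORD_FMT = "%.7f"  # round trips well inside the 1e-6 nm contract


def write_trajectory(traj: Trajectory, path: str | os.PathLike) -> None:
    """Write the canonical coordinate-table format (byte-stable)."""
    lines = [f"#interval {traj.frame_interval!r}"]
    boxes = np.array([f.box for f in traj.frames])
    constant_box = len(traj.frames) > 0 and np.all(boxes == boxes[0])
    if constant_box:
        lines.append("#box " + " ".join(_COORD_FMT % v for v in boxes[0]))
    for fi, frame in enumerate(traj.frames):
        if not constant_box:
            lines.append("#box " + " ".join(_COORD_FMT % v for v in frame.box))
        for pi, xyz in enumerate(frame.coordinates):
            lines.append(
                f"{fi} {pi} " + " ".join(_COORD_FMT % v for v in xyz)
            )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def _parse_coordinate_table(path: str | os.PathLike) -> Trajectory:
    interval = None
    boxes: list[np.ndarray] = []
    rows: dict[int, list[tuple[int, float, float, float]]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip() if not raw.startswith("#") else raw.strip()
            if not line:
                continue
            if line.startswith("#interval"):
                interval = float(line.split()[1])
                continue
            if line.startswith("#box"):
                vals = [float(v) for v in line.split()[1:]]
                if len(vals) != 3:
                    raise MalformedInputError(
                        f"{path}:{lineno}: #box needs exactly 3 orthorhombic edges "
                        "(triclinic boxes are not supported)"
                    )
                boxes.append(np.array(vals))
                continue
            if line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 5:
                raise MalformedInputError(
                    f"{path}:{lineno}: expected 'frame particle x y z', got {line!r}"
                )
            fi, pi = int(parts[0]), int(parts[1])
            rows.setdefault(fi, []).append(
                (pi, float(parts[2]), float(parts[3]), float(parts[4]))
            )
    if interval is None:
        raise MalformedInputError(f"{path}: missing '#interval' header")
    if not boxes:
        if rows:
            raise MalformedInputError(f"{path}: missing '#box' header")
        return Trajectory(frames=[], frame_interval=interval)

    frame_ids = sorted(rows)
    expected = list(range(frame_ids[0], frame_ids[0] + len(frame_ids)))
    if frame_ids != expected:
        missing = sorted(set(expected) - set(frame_ids))[0]
        raise MalformedInputError(
            f"{path}: frame indices are not consecutive — gap at frame {missing} "
            f"(declared interval {interval:g} ns)"
        )
    if len(boxes) == 1:
        boxes = boxes * len(frame_ids)
    elif len(boxes) != len(frame_ids):
        raise MalformedInputError(
            f"{path}: {len(boxes)} #box lines for {len(frame_ids)} frames "
            "(need 1 or one per frame)"
        )

    frames = []
    for fi, box in zip(frame_ids, boxes):
        entries = rows[fi]
        indices = [e[0] for e in entries]
        if len(set(indices)) != len(indices):
            dup = [i for i in set(indices) if indices.count(i) > 1][0]
            raise MalformedInputError(
                f"{path}: frame {fi} lists particle {dup} more than once"
            )
        coords = np.zeros((len(entries), 3))
        seen = sorted(indices)
        if seen != list(range(len(entries))):
            raise MalformedInputError(
                f"{path}: frame {fi} particle indices are not 0..N-1"
            )
        for pi, x, y, z in entries:
            coords[pi] = (x, y, z)
        frames.append(BoxedFrame(time=fi * interval, coordinates=coords, box=box))
    return Trajectory(frames=frames, frame_interval=interval)


def read_trajectory(
    path: str | os.PathLike,
    format: str = "auto",
    frame_interval: float | None = None,
) -> Trajectory:
    """Read a trajectory, normalizing units to nm and ns.

    ``format='table'`` reads the canonical text format. ``format='mdanalysis'``
    hands any MDAnalysis-readable single file (PDB, GRO, multi-frame PDB ...)
    to MDAnalysis and converts Å→nm, ps→ns; it requires ``frame_interval``
    when the file itself carries no time step. ``'auto'`` picks by extension.
    """
    if not os.path.exists(path):
        raise MalformedInputError(f"trajectory file not found: {path}")
    if format == "auto":
        ext = os.path.splitext(str(path))[1].lower()
        format = "table" if ext in ("", ".txt", ".traj", ".dat", ".tsv") else "mdanalysis"
    if format == "table":
        return _parse_coordinate_table(path)
    if format == "mdanalysis":
        return _read_with_mdanalysis(path, frame_interval)
    raise UsageError(f"unknown trajectory format {format!r}")


def _read_with_mdanalysis(path, frame_interval):
    import MDAnalysis as mda  # optional dependency

    u = mda.Universe(str(path))
    frames = []
    for ts in u.trajectory:
        if ts.dimensions is None:
            raise MalformedInputError(f"{path}: frames carry no box information")
        lx, ly, lz, alpha, beta, gamma = ts.dimensions
        if not np.allclose([alpha, beta, gamma], 90.0, atol=1e-3):
            raise MalformedInputError(
                f"{path}: triclinic box (angles {alpha:g}/{beta:g}/{gamma:g}) "
                "is not supported; orthorhombic boxes only"
            )
        frames.append(
            BoxedFrame(
                time=ts.time / 1000.0,  # ps → ns
                coordinates=ts.positions / 10.0,  # Å → nm
                box=np.array([lx, ly, lz]) / 10.0,
            )
        )
    if frame_interval is None:
        times = np.array([f.time for f in frames])
        if len(times) < 2 or np.allclose(np.diff(times), 0):
            raise MalformedInputError(
                f"{path}: no usable time step in file; pass frame_interval"
            )
        frame_interval = float(times[1] - times[0])
    else:
        for i, f in enumerate(frames):
            f.time = i * frame_interval
    return Trajectory(frames=frames, frame_interval=frame_interval)


# ---------------------------------------------------------------------------
# topology tables and selections
# ---------------------------------------------------------------------------


def _parse_leaflet(token: str) -> tuple[int, str]:
    t = token.lower()
    if t in ("upper", "lower"):
        return 1, t
    for sep in ("_", "-", "."):
        if sep in t:
            a, b = t.split(sep, 1)
            if a.startswith("m") and b in ("upper", "lower"):
                return int(a[1:]), b
            if b.startswith("m") and a in ("upper", "lower"):
                return int(b[1:]), a
    raise MalformedInputError(f"cannot parse leaflet label {token!r}")


def read_topology(path: str | os.PathLike) -> list[dict]:
    """Read a topology table into row dicts (see module docstring for format)."""
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 6:
                raise MalformedInputError(
                    f"{path}:{lineno}: expected "
                    "'particle molecule kind leaflet role mass'"
                )
            rows.append(
                {
                    "particle_index": int(parts[0]),
                    "molecule_id": parts[1],
                    "kind": parts[2],
                    "leaflet": parts[3],
                    "role": parts[4],
                    "mass": float(parts[5]),
                }
            )
    return rows


def build_selections(
    topology: list[dict], n_particles: int | None = None
) -> list[MoleculeSelection]:
    """Group topology rows into per-molecule selections.

    Every particle must belong to exactly one molecule; the returned
    selections partition the particle set. Order follows first appearance.
    """
    seen: dict[int, str] = {}
    per_mol: dict[str, dict] = {}
    for row in topology:
        pi = row["particle_index"]
        if pi in seen:
            raise StructuralError(
                f"particle {pi} assigned to both {seen[pi]!r} and {row['molecule_id']!r}"
            )
        seen[pi] = row["molecule_id"]
        if row["kind"] not in _KINDS:
            raise StructuralError(f"unknown kind {row['kind']!r} for particle {pi}")
        if row["role"] not in _ROLES:
            raise StructuralError(f"unknown role {row['role']!r} for particle {pi}")
        mol = per_mol.setdefault(
            row["molecule_id"],
            {
                "kind": row["kind"],
                "leaflet": row["leaflet"],
                "tip": [],
                "tail": [],
                "tail_mass": [],
                "other": [],
            },
        )
        if mol["kind"] != row["kind"] or mol["leaflet"] != row["leaflet"]:
            raise StructuralError(
                f"molecule {row['molecule_id']!r} has inconsistent kind/leaflet rows"
            )
        if row["role"] == "tip":
            mol["tip"].append(pi)
        elif row["role"] == "tail":
            mol["tail"].append(pi)
            mol["tail_mass"].append(row["mass"])
        else:
            mol["other"].append(pi)

    if n_particles is not None:
        missing = set(range(n_particles)) - set(seen)
        if missing:
            raise StructuralError(
                f"{len(missing)} particles have no molecule (first: {min(missing)})"
            )
        out_of_range = [pi for pi in seen if pi >= n_particles]
        if out_of_range:
            raise StructuralError(
                f"particle index {min(out_of_range)} exceeds particle count {n_particles}"
            )

    selections = []
    for mol_id, mol in per_mol.items():
        membrane, leaflet = _parse_leaflet(mol["leaflet"])
        selections.append(
            MoleculeSelection(
                molecule_id=mol_id,
                kind=mol["kind"],
                membrane=membrane,
                leaflet=leaflet,
                tip_heavy_atoms=np.array(sorted(mol["tip"]), dtype=int),
                tail_atoms=np.array(mol["tail"], dtype=int),
                tail_masses=np.array(
                    [m for _, m in sorted(zip(mol["tail"], mol["tail_mass"]))]
                ),
                other_atoms=np.array(sorted(mol["other"]), dtype=int),
            )
        )
        # keep tail atom order sorted alongside masses
        sel = selections[-1]
        order = np.argsort(sel.tail_atoms)
        sel.tail_atoms = sel.tail_atoms[order]
    return selections


def glycolipids_per_leaflet(selections: list[MoleculeSelection]) -> dict[tuple[int, str], int]:
    """Count glycolipids per (membrane, leaflet) — bookkeeping report."""
    counts: dict[tuple[int, str], int] = {}
    for sel in selections:
        if sel.kind == "glycolipid":
            counts[sel.leaflet_key] = counts.get(sel.leaflet_key, 0) + 1
    return counts
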