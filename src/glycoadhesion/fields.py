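"""Patch-resolved membrane height fields, separations, roughness, and
lateral correlations.

The simulation x-y plane is divided into n_x × n_y quadratic patches
(default 16×16). For each patch and each monolayer, the mass-weighted
center of mass of the lipid-tail atoms defines a monolayer height; the
membrane midplane of a patch is the mean of its two monolayer heights.
Two apposing membranes at the same x-y position define two local
separations (one per aqueous gap) that add up exactly to the box height.

The membrane roughness xi_perp is the standard deviation of the local
separation l about its mean l_bar, pooled over patches, frames, and both
gaps (the two aqueous compartments are statistically equivalent by
construction). The lateral correlation function C(r) of delta_l = l - l_bar
is evaluated at multiples of the patch side along x and y, pooled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import (
    GeometryError,
    StructuralError,
    UndefinedEstimateError,
    UsageError,
)
from .trajectory import BoxedFrame, MoleculeSelection, Trajectory

__all__ = [
    "PatchGrid",
    "SeparationField",
    "RoughnessEstimate",
    "SeparationHistogram",
    "LateralCorrelation",
    "compute_patch_grid",
    "local_separations",
    "separation_fields",
    "roughness",
    "roughness_series",
    "smoothed_roughness_series",
    "separation_histogram",
    "map_bonds_to_patches",
    "anchor_positions",
    "lateral_correlation",
    "pool_lateral_correlations",
]

logger = logging.getLogger(__name__)

DEFAULT_GRID = 16


@dataclass
class PatchGrid:
    """Per-patch monolayer tail-COM heights and midplane for one membrane.

    ``monolayer_z`` has shape (2, n_x, n_y) ordered (lower, upper);
    ``midplane`` is their mean. ``filled`` marks patches whose value was
    reconstructed by periodic nearest-neighbour averaging because no tail
    atom fell into them.
    """

    n_x: int
    n_y: int
    patch_side_x: float
    patch_side_y: float
    monolayer_z: np.ndarray
    midplane: np.ndarray
    filled: np.ndarray

    @property
    def patch_area(self) -> float:
        return self.patch_side_x * self.patch_side_y


@dataclass
class SeparationField:
    """Local separations l(x, y) per frame and gap: shape (n_frames, n_gaps, n_x, n_y).

    ``box_heights`` holds Lz per frame; for two-membrane systems the two
    gaps sum to Lz at every patch.
    """

    l: np.ndarray
    box_heights: np.ndarray
    patch_side_x: float
    patch_side_y: float
    frame_interval: float = 0.1
    trajectory_id: str = "traj"

    def __post_init__(self) -> None:
        self.l = np.asarray(self.l, dtype=float)
        self.box_heights = np.asarray(self.box_heights, dtype=float)
        if self.l.ndim != 4:
            raise StructuralError("separation field must be (frames, gaps, n_x, n_y)")
        if self.box_heights.shape != (self.l.shape[0],):
            raise StructuralError("need one box height per frame")

    @property
    def n_frames(self) -> int:
        return self.l.shape[0]

    @property
    def n_gaps(self) -> int:
        return self.l.shape[1]

    def pooled_mean(self) -> float:
        return float(self.l.mean())


@dataclass
class RoughnessEstimate:
    xi_perp: float
    l_bar: float
    per_trajectory: list[float] = field(default_factory=list)
    sem: float = float("nan")


@dataclass
class SeparationHistogram:
    bin_edges: np.ndarray
    density: np.ndarray
    condition: str
    gauss_mean: float | None
    gauss_sd: float | None
    n_samples: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class LateralCorrelation:
    offsets: np.ndarray  # nm, multiples of the patch side
    C: np.ndarray  # normalized, C(0) = 1
    variance: float  # un-normalized C(0) = xi_perp^2
    sem: np.ndarray | None = None


# ---------------------------------------------------------------------------


def _fill_empty_patches(z: np.ndarray, empty: np.ndarray) -> np.ndarray:
    """Replace empty patches by the mean of their filled periodic 4-neighbours,
    iterating so that isolated clusters also resolve."""
    z = z.copy()
    empty = empty.copy()
    while empty.any():
        neigh_sum = np.zeros_like(z)
        neigh_n = np.zeros(z.shape, dtype=int)
        for axis in (0, 1):
            for shift in (1, -1):
                nz = np.roll(z, shift, axis=axis)
                ok = ~np.roll(empty, shift, axis=axis)
                neigh_sum += np.where(ok, nz, 0.0)
                neigh_n += ok
        fixable = empty & (neigh_n > 0)
        if not fixable.any():
            raise GeometryError("no filled patches available to reconstruct from")
        z[fixable] = neigh_sum[fixable] / neigh_n[fixable]
        empty[fixable] = False
    return z


def compute_patch_grid(
    frame: BoxedFrame,
    selections: list[MoleculeSelection],
    membrane: int = 1,
    n_x: int = DEFAULT_GRID,
    n_y: int = DEFAULT_GRID,
) -> PatchGrid:
    """Bin tail atoms of one membrane into patches and compute midplanes.

    Every tail atom maps to exactly one patch by periodic x-y wrapping of
    its own position; the patch/monolayer height is the mass-weighted mean
    tail z. Patches left empty in a monolayer are filled by periodic
    nearest-neighbour averaging and flagged.
    """
    lx, ly = frame.box[0], frame.box[1]
    monolayer_z = np.zeros((2, n_x, n_y))
    filled = np.zeros((2, n_x, n_y), dtype=bool)
    for li, leaflet in enumerate(("lower", "upper")):
        idx_parts, mass_parts = [], []
        for sel in selections:
            if sel.membrane == membrane and sel.leaflet == leaflet and sel.tail_atoms.size:
                idx_parts.append(sel.tail_atoms)
                mass_parts.append(sel.tail_masses)
        if not idx_parts:
            raise UsageError(
                f"no tail atoms for membrane {membrane} leaflet {leaflet!r}"
            )
        atoms = np.concatenate(idx_parts)
        masses = np.concatenate(mass_parts)
        xy = frame.coordinates[atoms, :2]
        z = frame.coordinates[atoms, 2]
        ix = np.floor(np.mod(xy[:, 0], lx) / lx * n_x).astype(int) % n_x
        iy = np.floor(np.mod(xy[:, 1], ly) / ly * n_y).astype(int) % n_y
        flat = ix * n_y + iy
        wsum = np.bincount(flat, weights=masses, minlength=n_x * n_y)
        wz = np.bincount(flat, weights=masses * z, minlength=n_x * n_y)
        empty = (wsum == 0).reshape(n_x, n_y)
        with np.errstate(invalid="ignore", divide="ignore"):
            zgrid = (wz / wsum).reshape(n_x, n_y)
        if empty.any():
            logger.warning(
                "membrane %d %s monolayer: %d empty patch(es) filled by "
                "periodic nearest-neighbour average",
                membrane,
                leaflet,
                int(empty.sum()),
            )
            zgrid = _fill_empty_patches(np.where(empty, 0.0, zgrid), empty)
        monolayer_z[li] = zgrid
        filled[li] = empty
    return PatchGrid(
        n_x=n_x,
        n_y=n_y,
        patch_side_x=lx / n_x,
        patch_side_y=ly / n_y,
        monolayer_z=monolayer_z,
        midplane=monolayer_z.mean(axis=0),
        filled=filled,
    )


def local_separations(grid1: PatchGrid, grid2: PatchGrid, lz: float) -> np.ndarray:
    """Two local separations per patch: gap1 = (mid2 - mid1) wrapped to (0, Lz),
    gap2 = Lz - gap1. Shape (2, n_x, n_y)."""
    if (grid1.n_x, grid1.n_y) != (grid2.n_x, grid2.n_y):
        raise StructuralError("membranes must share the patch grid")
    gap1 = np.mod(grid2.midplane - grid1.midplane, lz)
    if np.any(gap1 <= 0) or np.any(gap1 >= lz):
        raise GeometryError("membranes crossed: non-positive local separation")
    return np.stack([gap1, lz - gap1])


def separation_fields(
    traj: Trajectory,
    selections: list[MoleculeSelection],
    n_x: int = DEFAULT_GRID,
    n_y: int = DEFAULT_GRID,
) -> SeparationField:
    """Per-frame separation fields for a two-membrane trajectory.

    Single-membrane trajectories yield one gap equal to the box height
    everywhere (the monolayers of one membrane are coupled, so the local
    separation is the box height by construction).
    """
    membranes = sorted({s.membrane for s in selections})
    frames_l, heights = [], []
    psx = psy = None
    for frame in traj.frames:
        lz = frame.box[2]
        heights.append(lz)
        if membranes == [1, 2]:
            g1 = compute_patch_grid(frame, selections, membrane=1, n_x=n_x, n_y=n_y)
            g2 = compute_patch_grid(frame, selections, membrane=2, n_x=n_x, n_y=n_y)
            frames_l.append(local_separations(g1, g2, lz))
            psx, psy = g1.patch_side_x, g1.patch_side_y
        else:
            frames_l.append(np.full((1, n_x, n_y), lz))
            psx, psy = frame.box[0] / n_x, frame.box[1] / n_y
    return SeparationField(
        l=np.array(frames_l),
        box_heights=np.array(heights),
        patch_side_x=psx,
        patch_side_y=psy,
        frame_interval=traj.frame_interval,
        trajectory_id=traj.trajectory_id,
    )


# ---------------------------------------------------------------------------
# roughness
# ---------------------------------------------------------------------------


def roughness(
    fields: SeparationField | list[SeparationField],
    l_bar: float | None = None,
) -> RoughnessEstimate:
    """xi_perp = sqrt(<(l - l_bar)^2>) over gaps, patches, and frames.

    ``l_bar=None`` uses the pooled sample mean; passing a number fixes the
    reference separation instead. With several trajectories, per-trajectory
    values and their SEM are reported alongside the pooled estimate.
    """
    if isinstance(fields, SeparationField):
        fields = [fields]
    if not fields or all(f.l.size == 0 for f in fields):
        raise UndefinedEstimateError("empty separation field")
    pooled = np.concatenate([f.l.ravel() for f in fields])
    mean = float(pooled.mean()) if l_bar is None else float(l_bar)
    xi = float(np.sqrt(np.mean((pooled - mean) ** 2)))
    per = [
        float(np.sqrt(np.mean((f.l - (f.l.mean() if l_bar is None else mean)) ** 2)))
        for f in fields
        if f.l.size
    ]
    sem = float("nan")
    if len(per) >= 2:
        sem = float(np.std(per, ddof=1) / np.sqrt(len(per)))
    return RoughnessEstimate(xi_perp=xi, l_bar=mean, per_trajectory=per, sem=sem)


def roughness_series(field: SeparationField) -> np.ndarray:
    """Per-frame roughness about the frame's own mean separation Lz/2.

    For two equal-weight gaps the per-frame mean separation is exactly half
    the box height, so each conformation's roughness is well defined.
    """
    if field.l.size == 0:
        raise UndefinedEstimateError("empty separation field")
    ref = (field.box_heights / field.n_gaps)[:, None, None, None]
    return np.sqrt(np.mean((field.l - ref) ** 2, axis=(1, 2, 3)))


def smoothed_roughness_series(series: np.ndarray, window: int = 50) -> np.ndarray:
    """Centered moving average; the window truncates at the series ends."""
    if window < 1:
        raise UsageError("window must be >= 1")
    series = np.asarray(series, dtype=float)
    n = len(series)
    half_lo = (window - 1) // 2
    half_hi = window // 2
    csum = np.concatenate([[0.0], np.cumsum(series)])
    lo = np.clip(np.arange(n) - half_lo, 0, n)
    hi = np.clip(np.arange(n) + half_hi + 1, 0, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


# ---------------------------------------------------------------------------
# histograms
# ---------------------------------------------------------------------------


def _gauss(x, mu, sd):
    return np.exp(-((x - mu) ** 2) / (2 * sd**2)) / (np.sqrt(2 * np.pi) * sd)


def separation_histogram(
    fields: SeparationField | list[SeparationField],
    condition: str = "all",
    bond_maps: list[np.ndarray] | None = None,
    bin_width: float = 0.1,
    refine: bool = False,
) -> SeparationHistogram:
    """Normalized density P(l), with a Gaussian fit from sample moments.

    ``condition='trans-bond'`` restricts to patches flagged in ``bond_maps``
    (one boolean (n_gaps, n_x, n_y) map per frame, concatenated over the
    supplied trajectories). ``refine=True`` polishes (mean, sd) by least
    squares against the binned density.
    """
    if isinstance(fields, SeparationField):
        fields = [fields]
    values = []
    maps_iter = iter(bond_maps) if bond_maps is not None else None
    for f in fields:
        for fi in range(f.n_frames):
            frame_l = f.l[fi]
            if condition == "all":
                values.append(frame_l.ravel())
            elif condition == "trans-bond":
                if maps_iter is None:
                    raise UsageError("trans-bond condition needs bond_maps")
                m = next(maps_iter)
                if m.shape != frame_l.shape:
                    raise StructuralError("bond map shape mismatch")
                values.append(frame_l[m])
            else:
                raise UsageError(f"unknown condition {condition!r}")
    samples = np.concatenate(values) if values else np.empty(0)
    if samples.size == 0:
        raise UndefinedEstimateError(f"no separations satisfy condition {condition!r}")
    lo = np.floor(samples.min() / bin_width) * bin_width
    hi = np.ceil(samples.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    density, edges = np.histogram(samples, bins=edges, density=True)
    mu = float(samples.mean())
    sd = float(samples.std())
    if sd == 0.0:
        return SeparationHistogram(edges, density, condition, None, None, samples.size)
    if refine:
        centers = 0.5 * (edges[:-1] + edges[1:])
        try:
            (mu, sd), _ = curve_fit(_gauss, centers, density, p0=(mu, sd))
            sd = abs(float(sd))
            mu = float(mu)
        except RuntimeError:  # keep the moment fit if the refinement stalls
            pass
    return SeparationHistogram(edges, density, condition, mu, sd, samples.size)


# ---------------------------------------------------------------------------
# bond-to-patch mapping
# ---------------------------------------------------------------------------


def anchor_positions(
    frame: BoxedFrame, selections: list[MoleculeSelection], molecule_ids: list[str]
) -> np.ndarray:
    """Wrapped x-y tail-COM anchor position per requested glycolipid."""
    by_id = {s.molecule_id: s for s in selections}
    out = np.zeros((len(molecule_ids), 2))
    for i, mid in enumerate(molecule_ids):
        sel = by_id[mid]
        if sel.tail_atoms.size == 0:
            raise UsageError(f"molecule {mid!r} has no tail atoms for anchoring")
        xy = frame.coordinates[sel.tail_atoms, :2]
        w = sel.tail_masses / sel.tail_masses.sum()
        out[i] = np.mod((w[:, None] * xy).sum(axis=0), frame.box[:2])
    return out


def map_bonds_to_patches(
    traj: Trajectory,
    selections: list[MoleculeSelection],
    binding_events: dict[str, list],
    pairs: dict[str, tuple[str, str]],
    n_x: int = DEFAULT_GRID,
    n_y: int = DEFAULT_GRID,
    n_gaps: int = 2,
    mark: str = "both-anchors",
) -> list[np.ndarray]:
    """Per-frame boolean patch maps of trans-bound glycolipid anchors.

    For each frame, patches containing the anchor (wrapped x-y tail COM) of
    a glycolipid currently inside a trans binding event are marked, in both
    gap layers (a bond at a patch conditions that patch's separation in
    both compartments, which hold the same l up to the gap-sum constraint;
    the first gap layer is the interacting interface). ``mark='first-anchor'``
    marks only the first partner's patch.
    """
    n_frames = len(traj.frames)
    active: dict[str, np.ndarray] = {}
    for pid, events in binding_events.items():
        mask = np.zeros(n_frames, dtype=bool)
        for ev in events:
            mask[ev.start_frame : ev.end_frame + 1] = True
        active[pid] = mask
    maps = []
    for fi, frame in enumerate(traj.frames):
        m = np.zeros((n_gaps, n_x, n_y), dtype=bool)
        mols = []
        for pid, (a, b) in pairs.items():
            if pid in active and active[pid][fi]:
                mols.extend([a, b] if mark == "both-anchors" else [a])
        if mols:
            xy = anchor_positions(frame, selections, mols)
            ix = np.floor(xy[:, 0] / frame.box[0] * n_x).astype(int) % n_x
            iy = np.floor(xy[:, 1] / frame.box[1] * n_y).astype(int) % n_y
            m[:, ix, iy] = True
        maps.append(m)
    return maps


# ---------------------------------------------------------------------------
# lateral correlation
# ---------------------------------------------------------------------------


def lateral_correlation(
    fields: SeparationField | list[SeparationField],
    l_bar: float | None = None,
) -> LateralCorrelation:
    """Normalized correlation C(r) of delta_l at lattice offsets along x and y.

    C(r) = <delta_l(x) delta_l(x + r)> / <delta_l^2>, averaged over patches
    (periodically), both lattice axes, frames, and gaps. With several
    trajectories the pooled estimate carries an SEM over per-trajectory
    curves. The un-normalized zero-offset value equals xi_perp^2 exactly.
    """
    if isinstance(fields, SeparationField):
        fields = [fields]
    if not fields:
        raise UndefinedEstimateError("no separation fields")
    n_x = fields[0].l.shape[2]
    n_off = n_x // 2 + 1
    per_curves, per_var = [], []
    mean = (
        float(np.concatenate([f.l.ravel() for f in fields]).mean())
        if l_bar is None
        else float(l_bar)
    )
    for f in fields:
        d = f.l - mean
        acc = np.zeros(n_off)
        for k in range(n_off):
            cx = d * np.roll(d, k, axis=2)
            cy = d * np.roll(d, k, axis=3)
            acc[k] = 0.5 * (cx.mean() + cy.mean())
        per_curves.append(acc)
        per_var.append(acc[0])
    pooled = np.average(per_curves, axis=0, weights=[f.l.size for f in fields])
    variance = float(pooled[0])
    if variance <= 0:
        raise UndefinedEstimateError("zero variance: correlation undefined")
    C = pooled / variance
    sem = None
    if len(per_curves) >= 2:
        normed = [c / c[0] for c in per_curves if c[0] > 0]
        if len(normed) >= 2:
            sem = np.std(normed, axis=0, ddof=1) / np.sqrt(len(normed))
    offsets = np.arange(n_off) * fields[0].patch_side_x
    return LateralCorrelation(offsets=offsets, C=C, variance=variance, sem=sem)


def pool_lateral_correlations(fields: list[SeparationField]) -> LateralCorrelation:
    return lateral_correlation(fields)
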