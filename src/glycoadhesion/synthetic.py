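"""Synthetic trajectories and contact series with analytically known truth.

Every analysis stage in this package needs a ground-truth oracle, so the
generator plants structure whose statistics are available in closed form:

* Membrane height fields are sampled from the Helfrich equilibrium
  spectrum <|h_q|^2> = k_B T / (A (kappa q^4 + gamma q^2)) on the discrete
  mode grid of the patch lattice, with tension gamma = 0 by default (the
  zero-tension ensemble of a semi-isotropically coupled membrane at 1 bar).
  The relative roughness of two independent membranes follows as a
  closed-form mode sum. Frames are independent by default; an optional
  Ornstein-Uhlenbeck evolution with mode relaxation times tau_q produces
  temporally correlated trajectories whose per-trajectory means genuinely
  differ, as they do for slowly relaxing membranes.
* Contact-count series come from a two-state (bound/unbound) Markov chain
  per glycolipid pair with exact stationary bound probability
  P_b = k_on/(k_on + k_off). Bound frames emit shifted-Poisson counts that
  always reach the binding cutoff; unbound frames emit occasional
  sub-threshold "collision" counts — the fuzzy-binding phenomenology the
  event classifier has to cope with.
* Geometric-tip trajectories anchor rigid pseudo-atom tip blobs on
  laterally diffusing glycolipids of two apposing leaflets; trans contacts
  arise only where the fluctuating local separation is small enough for
  the tips to overlap, so binding frequency rises with roughness.

Reduced units: k_B T = 1; lengths nm, times ns. All randomness flows from
a single integer seed through numpy Generators; identical parameters and
seed give bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
import warnings

import numpy as np

from .contacts import ContactSeries
from .errors import GeometryError, NumericError, UsageError
from .trajectory import BoxedFrame, MoleculeSelection, PairSpec, Trajectory

__all__ = [
    "HelfrichParams",
    "KineticParams",
    "SyntheticTruth",
    "helfrich_closed_form_roughness",
    "helfrich_closed_form_correlation",
    "sample_height_field",
    "simulate_membrane_pair",
    "simulate_binding_kinetics",
    "simulate_geometric_tips",
]

DEFAULT_KAPPA = 15.0  # k_B T; PC-bilayer range, ~0.5 nm roughness at the default box


@dataclass
class HelfrichParams:
    """Helfrich fluctuation spectrum on the discrete patch-mode grid.

    kappa: bending rigidity (k_B T); gamma: tension (k_B T / nm^2, default 0);
    box_x/box_y: lateral box (nm); n_x/n_y: mode/patch grid; tau0: optional
    relaxation time (ns) of the slowest mode for Ornstein-Uhlenbeck frame
    coupling, scaled to faster modes as tau_q = tau0 (q_1/q)^2; None means
    independent frames.
    """

    kappa: float = DEFAULT_KAPPA
    gamma: float = 0.0
    box_x: float = 24.1
    box_y: float = 24.1
    n_x: int = 16
    n_y: int = 16
    kBT: float = 1.0
    tau0: float | None = None

    def __post_init__(self) -> None:
        if self.kappa < 0 or self.gamma < 0:
            raise UsageError("kappa and gamma must be non-negative")
        if self.kappa == 0 and self.gamma == 0:
            raise NumericError("kappa = gamma = 0: spectrum diverges")

    def mode_grid(self) -> tuple[np.ndarray, np.ndarray]:
        qx = 2 * np.pi * np.fft.fftfreq(self.n_x, d=self.box_x / self.n_x)
        qy = 2 * np.pi * np.fft.fftfreq(self.n_y, d=self.box_y / self.n_y)
        return np.meshgrid(qx, qy, indexing="ij")

    def spectrum(self) -> np.ndarray:
        """Per-mode variance <|h_q|^2>; the q = 0 mode carries no weight."""
        qxg, qyg = self.mode_grid()
        q2 = qxg**2 + qyg**2
        area = self.box_x * self.box_y
        with np.errstate(divide="ignore", invalid="ignore"):
            s = self.kBT / (area * (self.kappa * q2**2 + self.gamma * q2))
        s[0, 0] = 0.0
        return s


@dataclass
class KineticParams:
    """Two-state binding kinetics with a fuzzy contact-emission law.

    Rates in 1/ns. Bound frames emit ``bound_offset + Poisson(mu_b)``
    contacts (the offset keeps every bound frame at or above the default
    binding cutoff n_c = 5, so classification is exact). Unbound frames
    emit, with probability ``p_coll``, a collision of
    ``1 + min(Poisson(mu_coll), bound_offset - 2)`` contacts — always
    sub-threshold — and otherwise zero.
    """

    k_on: float = 0.43
    k_off: float = 1.0
    mu_b: float = 4.0
    bound_offset: int = 5
    p_coll: float = 0.02
    mu_coll: float = 1.0
    frame_interval: float = 0.1
    area: float = 23.3

    def __post_init__(self) -> None:
        if self.k_on < 0 or self.k_off < 0:
            raise UsageError("rates must be non-negative")
        if self.bound_offset < 2:
            raise UsageError("bound_offset must be >= 2")
        if not 0 <= self.p_coll <= 1:
            raise UsageError("p_coll must be a probability")

    @property
    def stationary_P_b(self) -> float:
        total = self.k_on + self.k_off
        return self.k_on / total if total > 0 else 0.0


@dataclass
class SyntheticTruth:
    """Planted parameters and closed-form targets of a generated dataset."""

    seeds: list[int] = field(default_factory=list)
    xi_perp: float | None = None
    l_mean: float | None = None
    correlation: list[float] | None = None
    P_b: float | None = None
    K: float | None = None
    params: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# Helfrich closed forms and sampling
# ---------------------------------------------------------------------------


def helfrich_closed_form_roughness(p: HelfrichParams) -> float:
    """Relative roughness of two independent membranes, xi_perp (nm).

    Var(h) per membrane is the mode sum of the spectrum; the separation
    involves h_2 - h_1, so its variance is twice that.
    """
    return float(np.sqrt(2.0 * p.spectrum().sum()))


def helfrich_closed_form_correlation(p: HelfrichParams, normalized: bool = True) -> np.ndarray:
    """Planted correlation of the separation field at x-lattice offsets.

    Cov(d(0), d(r)) = 2 sum_q S_q cos(q_x r) at r = k * patch_side,
    k = 0 .. n_x // 2.
    """
    s = p.spectrum()
    qxg, _ = p.mode_grid()
    side = p.box_x / p.n_x
    ks = np.arange(p.n_x // 2 + 1)
    cov = np.array([2.0 * np.sum(s * np.cos(qxg * k * side)) for k in ks])
    return cov / cov[0] if normalized else cov


def sample_height_field(
    p: HelfrichParams, n_frames: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample (n_frames, n_x, n_y) Gaussian height fields from the spectrum.

    Independent frames unless tau0 is set, in which case each mode follows
    a stationary Ornstein-Uhlenbeck process with relaxation time
    tau_q = tau0 (q_1 / q)^2 sampled at ``p`` frame spacing stored by the
    caller (the OU step uses the frame index as the clock; pass dt through
    tau0 in frame units or via :func:`simulate_membrane_pair`).
    """
    return _sample_height_field(p, n_frames, rng, dt=None)


def _sample_height_field(p, n_frames, rng, dt):
    s = p.spectrum()
    amp = np.sqrt(s)
    n = p.n_x * p.n_y

    def draw():
        return (
            rng.standard_normal((p.n_x, p.n_y)) + 1j * rng.standard_normal((p.n_x, p.n_y))
        ) / np.sqrt(2.0)

    if p.tau0 is None or dt is None:
        fields = np.empty((n_frames, p.n_x, p.n_y))
        for t in range(n_frames):
            fields[t] = np.sqrt(2.0) * np.real(np.fft.ifft2(amp * draw()) * n)
        return fields
    qxg, qyg = p.mode_grid()
    q = np.sqrt(qxg**2 + qyg**2)
    q1 = 2 * np.pi / max(p.box_x, p.box_y)
    with np.errstate(divide="ignore"):
        tau_q = np.where(q > 0, p.tau0 * (q1 / q) ** 2, np.inf)
    decay = np.exp(-dt / tau_q)
    decay[0, 0] = 1.0
    w = draw()
    fields = np.empty((n_frames, p.n_x, p.n_y))
    for t in range(n_frames):
        if t > 0:
            w = decay * w + np.sqrt(1.0 - decay**2) * draw()
        fields[t] = np.sqrt(2.0) * np.real(np.fft.ifft2(amp * w) * n)
    return fields


# ---------------------------------------------------------------------------
# membrane-pair trajectories of tail pseudo-atoms
# ---------------------------------------------------------------------------


def _membrane_selection_rows(p: HelfrichParams, thickness: float):
    """Molecule bookkeeping for the 4 monolayers of tail pseudo-atoms."""
    selections = []
    index = 0
    for m in (1, 2):
        for leaflet in ("lower", "upper"):
            for i in range(p.n_x):
                for j in range(p.n_y):
                    selections.append(
                        MoleculeSelection(
                            molecule_id=f"m{m}{leaflet[0]}_{i:02d}_{j:02d}",
                            kind="lipid",
                            membrane=m,
                            leaflet=leaflet,
                            tip_heavy_atoms=np.empty(0, dtype=int),
                            tail_atoms=np.array([index]),
                            tail_masses=np.array([1.0]),
                        )
                    )
                    index += 1
    return selections


def simulate_membrane_pair(
    p: HelfrichParams | None = None,
    l_mean: float = 7.7,
    n_frames: int = 1000,
    seed: int = 0,
    thickness: float = 3.8,
    frame_interval: float = 0.15,
    trajectory_id: str | None = None,
) -> tuple[Trajectory, list[MoleculeSelection], SyntheticTruth]:
    """Two fluctuating membranes as tail pseudo-atom trajectories.

    Each patch of each monolayer holds one unit-mass pseudo-atom at the
    patch centre, at the planted midplane +/- thickness/2, so
    ``compute_patch_grid`` reconstructs the planted fields exactly. The box
    height is 2 * l_mean (two equal aqueous compartments); membrane 1 sits
    at Lz/4, membrane 2 at 3 Lz/4.
    """
    p = p or HelfrichParams()
    rng = np.random.default_rng(seed)
    h1 = _sample_height_field(p, n_frames, rng, dt=frame_interval)
    h2 = _sample_height_field(p, n_frames, rng, dt=frame_interval)
    lz = 2.0 * l_mean
    gap1 = l_mean + h2 - h1
    if np.any(gap1 <= thickness) or np.any(lz - gap1 <= thickness):
        worst = float(min(gap1.min(), (lz - gap1).min()))
        raise GeometryError(
            f"membranes overlap: minimum local gap {worst:.3f} nm <= membrane "
            f"thickness {thickness} nm; reduce roughness (raise kappa) or l_mean"
        )
    selections = _membrane_selection_rows(p, thickness)
    psx, psy = p.box_x / p.n_x, p.box_y / p.n_y
    xc = (np.arange(p.n_x) + 0.5) * psx
    yc = (np.arange(p.n_y) + 0.5) * psy
    xg, yg = np.meshgrid(xc, yc, indexing="ij")
    xy = np.column_stack([xg.ravel(), yg.ravel()])
    box = np.array([p.box_x, p.box_y, lz])
    z1 = lz / 4.0
    frames = []
    for t in range(n_frames):
        zs = []
        for m, h, base in ((1, h1[t], z1), (2, h2[t], z1 + l_mean)):
            mid = base + h
            for sign in (-1.0, +1.0):  # lower, upper monolayer
                zs.append((mid + sign * thickness / 2.0).ravel())
        coords = np.empty((4 * p.n_x * p.n_y, 3))
        coords[:, :2] = np.tile(xy, (4, 1))
        coords[:, 2] = np.concatenate(zs)
        frames.append(BoxedFrame(time=t * frame_interval, coordinates=coords, box=box))
    traj = Trajectory(
        frames=frames,
        frame_interval=frame_interval,
        trajectory_id=trajectory_id or f"helfrich_seed{seed}",
    )
    truth = SyntheticTruth(
        seeds=[seed],
        xi_perp=helfrich_closed_form_roughness(p),
        l_mean=l_mean,
        correlation=list(helfrich_closed_form_correlation(p)),
        params={
            "kappa": p.kappa,
            "gamma": p.gamma,
            "box": [p.box_x, p.box_y, lz],
            "grid": [p.n_x, p.n_y],
            "tau0": p.tau0,
            "thickness": thickness,
            "n_frames": n_frames,
        },
    )
    return traj, selections, truth


# ---------------------------------------------------------------------------
# two-state binding kinetics
# ---------------------------------------------------------------------------


def simulate_binding_kinetics(
    p: KineticParams | None = None,
    n_frames: int = 10_000,
    n_pairs: int = 1,
    seed: int = 0,
) -> tuple[list[ContactSeries], SyntheticTruth]:
    """Contact series from independent two-state Markov chains per pair.

    Uses the exact discrete-time transition kernel of the continuous-time
    chain at the frame interval, so the stationary bound probability is
    exactly k_on / (k_on + k_off), independent of the sampling step.
    """
    p = p or KineticParams()
    rng = np.random.default_rng(seed)
    dt = p.frame_interval
    total = p.k_on + p.k_off
    pb = p.stationary_P_b
    if total > 0:
        relax = 1.0 - np.exp(-total * dt)
        p_u2b = pb * relax
        p_b2u = (1.0 - pb) * relax
    else:
        p_u2b = p_b2u = 0.0
    state = rng.random(n_pairs) < pb  # stationary initial condition
    states = np.empty((n_pairs, n_frames), dtype=bool)
    for t in range(n_frames):
        states[:, t] = state
        u = rng.random(n_pairs)
        flip = np.where(state, u < p_b2u, u < p_u2b)
        state = state ^ flip
    counts = np.zeros((n_pairs, n_frames), dtype=int)
    counts[states] = p.bound_offset + rng.poisson(p.mu_b, size=int(states.sum()))
    unbound = ~states
    coll = unbound & (rng.random((n_pairs, n_frames)) < p.p_coll)
    counts[coll] = 1 + np.minimum(
        rng.poisson(p.mu_coll, size=int(coll.sum())), p.bound_offset - 2
    )
    series = [
        ContactSeries(
            pair=PairSpec(f"pair{i:03d}", f"gA{i:03d}", f"gB{i:03d}", "trans"),
            counts=counts[i],
            frame_interval=dt,
        )
        for i in range(n_pairs)
    ]
    truth = SyntheticTruth(
        seeds=[seed],
        P_b=pb,
        K=p.area * pb / (1.0 - pb) if pb < 1 else float("inf"),
        params={
            "k_on": p.k_on,
            "k_off": p.k_off,
            "mu_b": p.mu_b,
            "bound_offset": p.bound_offset,
            "p_coll": p.p_coll,
            "mu_coll": p.mu_coll,
            "frame_interval": dt,
            "area": p.area,
            "n_frames": n_frames,
            "n_pairs": n_pairs,
        },
    )
    return series, truth


# ---------------------------------------------------------------------------
# geometric tips: fluctuation-gated trans contacts
# ---------------------------------------------------------------------------

# rigid tip blob: 5 pseudo-heavy-atoms, ~0.3 nm across, like a compact
# trisaccharide head seen at contact resolution
_BLOB_OFFSETS = np.array(
    [
        [0.0, 0.0, 0.0],
        [0.15, 0.0, 0.05],
        [-0.15, 0.0, 0.05],
        [0.0, 0.15, -0.05],
        [0.0, -0.15, -0.05],
    ]
)


def simulate_geometric_tips(
    p: HelfrichParams | None = None,
    l_mean: float = 7.7,
    n_glycolipids: int = 90,
    tether: float = 3.2,
    diffusion: float = 0.5,
    n_frames: int = 400,
    seed: int = 0,
    thickness: float = 3.8,
    frame_interval: float = 0.15,
) -> tuple[Trajectory, list[MoleculeSelection], SyntheticTruth]:
    """Membrane pair plus diffusing glycolipids with rigid tip blobs.

    Glycolipids sit in the two leaflets facing the first aqueous gap
    (membrane 1 upper, membrane 2 lower). Tips extend ``tether`` nm from
    the local midplane into the gap, so trans contacts require a local
    separation below roughly 2 * tether + blob extent: binding is gated by
    the shape fluctuations, and trajectories with larger roughness show
    more trans contacts. Defaults emulate a large adhering system: 90
    glycolipids per interacting leaflet and slow-mode relaxation (tau0 =
    60 ns) comparable to the trajectory length, so per-trajectory mean
    roughness genuinely varies between replicates.
    """
    p = p or HelfrichParams(tau0=60.0)
    if tether >= l_mean:
        warnings.warn(
            "tip tether length >= mean gap: permanent-contact regime", stacklevel=2
        )
    traj, selections, truth = simulate_membrane_pair(
        p,
        l_mean=l_mean,
        n_frames=n_frames,
        seed=seed,
        thickness=thickness,
        frame_interval=frame_interval,
        trajectory_id=f"tips_seed{seed}",
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7_919]))
    n_mem = traj.n_particles
    psx, psy = p.box_x / p.n_x, p.box_y / p.n_y
    n_blob = len(_BLOB_OFFSETS)
    atoms_per_glyco = 1 + n_blob  # one tail anchor + tip blob

    glyco_sel = []
    for g in range(2 * n_glycolipids):
        membrane = 1 if g < n_glycolipids else 2
        leaflet = "upper" if membrane == 1 else "lower"
        base = n_mem + g * atoms_per_glyco
        glyco_sel.append(
            MoleculeSelection(
                molecule_id=f"glyco_m{membrane}_{g % n_glycolipids:03d}",
                kind="glycolipid",
                membrane=membrane,
                leaflet=leaflet,
                tip_heavy_atoms=np.arange(base + 1, base + 1 + n_blob),
                tail_atoms=np.array([base]),
                tail_masses=np.array([1.0]),
            )
        )

    # lateral random walks of the anchors (periodic)
    xy = rng.random((2 * n_glycolipids, 2)) * np.array([p.box_x, p.box_y])
    step_sd = np.sqrt(2.0 * diffusion * frame_interval)
    new_frames = []
    for t, frame in enumerate(traj.frames):
        if t > 0:
            xy = np.mod(
                xy + rng.normal(0.0, step_sd, size=xy.shape), [p.box_x, p.box_y]
            )
        ix = np.floor(xy[:, 0] / psx).astype(int) % p.n_x
        iy = np.floor(xy[:, 1] / psy).astype(int) % p.n_y
        # planted monolayer/midplane heights live in the membrane pseudo-atoms
        lz = frame.box[2]
        mono = frame.coordinates[:n_mem, 2].reshape(4, p.n_x, p.n_y)
        mid1 = 0.5 * (mono[0] + mono[1])
        mid2 = 0.5 * (mono[2] + mono[3])
        coords = np.empty((n_mem + 2 * n_glycolipids * atoms_per_glyco, 3))
        coords[:n_mem] = frame.coordinates
        for g in range(2 * n_glycolipids):
            base = n_mem + g * atoms_per_glyco
            if g < n_glycolipids:  # membrane 1, upper leaflet, tip points up
                anchor_z = mid1[ix[g], iy[g]] + thickness / 2.0
                tip_z = mid1[ix[g], iy[g]] + tether
                sign = +1.0
            else:  # membrane 2, lower leaflet, tip points down
                anchor_z = mid2[ix[g], iy[g]] - thickness / 2.0
                tip_z = mid2[ix[g], iy[g]] - tether
                sign = -1.0
            coords[base] = (xy[g, 0], xy[g, 1], anchor_z)
            blob = _BLOB_OFFSETS * np.array([1.0, 1.0, sign])
            coords[base + 1 : base + 1 + n_blob] = (
                np.array([xy[g, 0], xy[g, 1], tip_z]) + blob
            )
        coords[:, 2] = np.mod(coords[:, 2], lz)
        new_frames.append(
            BoxedFrame(time=frame.time, coordinates=coords, box=frame.box)
        )
    full = Trajectory(
        frames=new_frames,
        frame_interval=frame_interval,
        trajectory_id=traj.trajectory_id,
    )
    truth.params.update(
        {
            "n_glycolipids": n_glycolipids,
            "tether": tether,
            "diffusion": diffusion,
            "blob_atoms": n_blob,
        }
    )
    return full, selections + glyco_sel, truth
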