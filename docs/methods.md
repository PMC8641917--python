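# Methods

## Scope and units

The package analyses trajectories of membranes carrying glycolipids —
contact statistics, interaction events, two-dimensional binding
constants, patch-resolved roughness and separation correlations — and
extracts lamellar periods from diffraction peak tables. Internal units
are nm, ns, and degrees; adapters convert on ingest (Å→nm, ps→ns for
MDAnalysis-read formats). Boxes are orthorhombic; triclinic input is
rejected rather than approximated, which keeps minimum-image logic exact
(component-wise rounding is the exact minimum image for orthorhombic
cells).

## Contacts and events

A contact is a pair of tip heavy atoms, one per glycolipid, at
minimum-image distance strictly below the cutoff (default 0.45 nm). The
minimum image is taken over all three axes, including z: in
single-membrane systems the trans partners interact across the periodic
z boundary, so z images are the physically interacting geometry. The tip
and tail atom sets are caller-supplied through the topology table — what
counts as "tip" (e.g. whether linker atoms belong to it) is a modelling
decision the data model does not make. Leaflet membership likewise comes
from the topology, never from z coordinates, which are unreliable under
large shape fluctuations.

Interaction events are maximal runs of nonzero contact counts; runs
touching the series boundaries count. An event is a *binding event* when
its maximum contact count reaches `n_c` (default 5; 10 offered as a
sensitivity setting — on fuzzy data the binding constant decreases
mildly with `n_c` because shallow events drop out). All frames of a
binding event count as bound, including frames whose instantaneous count
is below `n_c`.

Burn-in (default 10% for trans analyses, 20% for the single-cis-pair
analysis) is discarded *before* segmentation, so an event straddling the
cut is truncated at the cut and `P_b` is a pure function of the retained
window. `P_b` pools bound frames over independent trajectories; the
error of `K = A·P_b/(1−P_b)` is the SEM of per-trajectory `K` values.
Pooling first and transforming once avoids the convexity bias of
averaging per-trajectory `K`. The membrane area `A` for `K` is taken per
frame as `Lx·Ly` and averaged over retained frames when it comes from a
trajectory (semi-isotropic pressure coupling lets the box breathe);
generators carry a nominal area. For multi-glycolipid membranes, a
glycolipid is *engaged* at a frame when at least one of its trans pairs
is inside a binding event; `n_trans` counts distinct engaged molecules
(a bond-counting mode is available as a flag), and
`K_trans = A·n_trans/(N_g−n_trans)²` is the mass-action estimator.
Events are strictly pairwise; multimer structure appears only through
per-frame engagement sets.

## Patch fields, roughness, correlations

The x-y plane is divided into n_x × n_y patches (default 16×16, ≈1.5 nm
side for a 24.1 nm box, ≈3.5 molecules per patch per monolayer at usual
lipid densities). Every tail atom maps to one patch by periodic x-y
wrapping of its own position; the patch/monolayer height is the
mass-weighted mean tail z ("center of mass" read literally), and the
membrane midplane of a patch is the mean of its two monolayer heights.
Patches left empty in a monolayer — rare but possible at ~3.5 molecules
per patch — are filled by iterated periodic nearest-neighbour averaging,
flagged, and logged.

Two apposing membranes define two local separations per patch (one per
aqueous compartment), `gap₁ = (mid₂−mid₁) mod Lz` and `gap₂ = Lz−gap₁`;
their sum is the box height by construction, and both compartments enter
roughness and histograms with equal weight (they are statistically
equivalent). Roughness is `ξ⊥ = √⟨(l−l̄)²⟩` pooled over gaps, patches and
frames, with `l̄` the pooled sample mean by default (a fixed-`l̄` mode
exists; the per-frame roughness series uses the frame's own mean `Lz/2`,
which is exact for two equal-weight gaps). Separation histograms use
0.1 nm bins by default (≈5 bins per typical 0.5 nm roughness); the
Gaussian fit comes from sample moments, with an optional least-squares
refinement against the binned density, and is refused for degenerate
(zero-variance) data. The conditional ("trans-bond") histogram restricts
to patches containing the anchor (wrapped x-y tail COM) of a trans-bound
glycolipid; by default both partners' anchor patches are marked
(`first-anchor` is available), in both gap layers. The lateral
correlation `C(r) = ⟨δl(x)δl(x+r)⟩/⟨δl²⟩` is evaluated at multiples of
the patch side, pooled over both lattice axes, frames and gaps; its
un-normalized zero-offset value equals `ξ⊥²` exactly, and SEMs come from
per-trajectory curves.

## Synthetic generator

The generator exists to give every analysis stage a ground-truth oracle;
it does not attempt atomistic physics, water, or ion effects.

**Helfrich membranes.** Height fields are sampled on the patch-mode grid
from `⟨|h_q|²⟩ = k_BT/(A(κq⁴+γq²))`, with reduced units `k_BT = 1` and
tension `γ = 0` by default (the zero-tension ensemble of a membrane
coupled semi-isotropically at 1 bar). The relative roughness of two
independent membranes is the closed-form mode sum
`ξ⊥² = 2·Σ_{q≠0} k_BT/(A(κq⁴+γq²))`, and the planted correlation is
`2·Σ S_q cos(q·r)`. Default bending rigidity κ = 15 k_BT: inside the
physical 10–40 k_BT range for fluid PC bilayers, and giving ξ⊥ ≈ 0.55 nm
at the default 24.1 nm / 16×16 geometry — the regime where fluctuations
gate trans-binding at a 7.7 nm mean separation. Frames are independent
by default; an optional Ornstein–Uhlenbeck evolution with mode
relaxation times `τ_q = τ₀(q₁/q)²` produces temporally correlated
trajectories. Each patch of each monolayer carries one unit-mass
pseudo-atom at midplane ± thickness/2 (thickness 3.8 nm, a fluid PC
bilayer), so the patch analysis reconstructs the planted fields exactly
and the gap-sum identity holds to machine precision.

**Two-state kinetics.** Per pair, a bound/unbound Markov chain uses the
exact discrete-time kernel of the continuous-time two-state process at
the frame interval (0.1 ns), so the stationary bound probability is
exactly `k_on/(k_on+k_off)` regardless of sampling. Bound frames emit
`5 + Poisson(4)` contacts — every bound frame at or above the default
`n_c`, making classification exact — and unbound frames emit, with
probability 0.02, a sub-threshold collision of 1–4 contacts (the fuzzy
phenomenology the classifier must tolerate). Collisions adjacent to
bound runs merge into events and bias `P_b` upward by O(2·p_coll·
n_events/n_frames) ≈ 2·10⁻³ at the defaults; recovery tests therefore
use collision-free emissions, the regime in which state
misclassification is negligible, while the fuzzy default exercises the
`n_c` sensitivity.

**Geometric tips.** Glycolipids in the two leaflets facing one aqueous
gap carry rigid 5-atom tip blobs (~0.3 nm across) on 3.2 nm tethers
above the local midplane, with laterally diffusing anchors
(D = 0.5 nm²/ns — fast on purpose, to mix anchor positions at desk
scale). Trans contacts require a local separation below roughly
2·tether + blob extent ≈ 6.8 nm, about 1.6 standard deviations under the
7.7 nm mean, so binding is fluctuation-gated. Defaults emulate a large
adhering system: 90 glycolipids per interacting leaflet and τ₀ = 60 ns
at 60 ns trajectories, so per-trajectory mean roughness genuinely varies
between replicates (≈0.38–0.73 nm) as it does for slowly relaxing
membranes, and mean trans-bond counts per frame land in the 0.2–3 range.

**What the generator does not emulate:** molecular conformations and
their coupling to binding, protrusions and peristaltic modes below the
patch scale, Ca²⁺ effects, leaflet coupling, and any force-field
physics. Passing recovery tests therefore demonstrates the correctness
of the estimators under a Gaussian-field + Markov model of the data, not
the realism of that model for any particular chemistry.

## Diffraction

Input is a peak table (Ω, Γ, intensity); detector-image reduction is
instrument-specific and out of scope. Peaks failing the specular
condition `|Γ−2Ω| ≤ tol` (default 0.1°) are rejected. Orders are
assigned by ascending Γ starting at n = 1 unless provided — which
mis-indexes tables with a missing interior order, so curated tables
should carry explicit orders. Per-order periods `D_n = nλ/(2 sin(Γ_n/2))`
are averaged with intensity weights by default (uniform weights
available); the estimate is invariant under intensity rescaling.

## Numerical choices and degenerate inputs

- Strict `<` at the contact cutoff; boundary ties are measure-zero but
  need a rule.
- Coordinates are written with 7 decimals (round trip well inside
  1e-6 nm); trajectory output is byte-stable.
- SEMs require ≥2 trajectories and are reported as NaN/undefined
  otherwise, never silently as 0.
- Zero-variance fields refuse correlation normalization; empty
  conditional histogram sets, zero retained frames after burn-in, and
  `P_b = 1` raise distinct estimate errors rather than returning
  infinities.
- All randomness flows from integer seeds through numpy Generators;
  identical parameters and seed give bit-identical outputs. Pipeline
  stages expand one top-level seed deterministically per trajectory.

## Problem sizes

Tests and the acceptance script run at desk scale: 10 trajectories of
10⁴ frames for kinetic recovery, 10 × 10³ frames on the 16×16 grid for
roughness (measured ξ⊥ within ~0.3% of the closed form), 10 × 400 frames
with 90+90 glycolipids for the fluctuation-gating check, and 10³ random
frames for the brute-force contact oracle. These sizes keep every
stochastic check several SEM away from its threshold while completing in
minutes.

## Known limitations

- The patch midplane is a piecewise-constant (nearest-patch) field; no
  interpolation between patches.
- Naive z averaging assumes a membrane does not straddle the periodic z
  boundary; generators place membranes away from it.
- Order assignment in diffraction assumes consecutive visible orders.
- No kinetic rate estimation (k_on/k_off) from event statistics, no
  bending-rigidity fitting from trajectories, and no adhesion-energy or
  force calculations.
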