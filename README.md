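# glycoadhesion

Analysis of glycolipid-mediated membrane adhesion from particle
trajectories and neutron diffraction peak tables.

Glycolipids can glue lipid membranes together: the carbohydrate tips of
glycolipids anchored in *apposing* membrane leaflets bind in *trans*,
while tips in the *same* leaflet bind in *cis*. Because these
carbohydrate–carbohydrate interactions are weak and *fuzzy* — many
interconverting bound conformations instead of one stereospecific
complex — they are quantified statistically, from contact time series
along simulation trajectories, and they depend strongly on the local
membrane separation, which fluctuates with the membrane shape. This
package provides, for structural modellers working on membrane adhesion:

- **Contact statistics**: heavy-atom contacts between carbohydrate tips
  under full 3D periodic boundary conditions (cutoff 0.45 nm, strict `<`),
  per-pair contact time series at a fixed frame interval.
- **Event statistics and 2D binding constants**: maximal nonzero-contact
  runs (*interaction events*), classified as *binding events* when their
  maximum contact count reaches a cutoff `n_c` (default 5). The bound-frame
  fraction `P_b` of the post-burn-in window gives the area-dimensioned
  binding constant `K = A·P_b/(1−P_b)`; for membranes with `N_g`
  glycolipids per monolayer the mass-action estimator
  `K_trans = A·n_trans/(N_g−n_trans)²` uses the mean number of engaged
  glycolipids. Errors are SEMs over independent trajectories.
- **Membrane roughness and separation correlations**: 16×16 patch
  discretization, mass-weighted lipid-tail centers of mass per monolayer,
  patch midplanes, two local separations per patch that add up exactly to
  the box height, roughness `ξ⊥ = √⟨(l−l̄)²⟩`, conditional separation
  distributions `P(l)` with Gaussian fits, and lateral correlation
  functions of the separation field.
- **Synthetic ground truth**: a generator that samples membrane height
  fields from the Helfrich spectrum `⟨|h_q|²⟩ = k_BT/(A(κq⁴+γq²))`
  (closed-form roughness and correlation oracles), two-state Markov
  binding kinetics with exact planted `P_b` and `K`, and geometric tip
  blobs whose trans contacts are gated by the shape fluctuations.
- **Lamellar periods**: inversion of the Bragg condition
  `Γ = 2 arcsin(nλ/(2D))` on specular (`Γ = 2Ω`) diffraction peaks of
  membrane multilayers.

## Worked example

```python
import glycoadhesion as ga

params = ga.KineticParams(k_on=0.5, k_off=1.0)   # stationary P_b = 1/3
all_series = []
for seed in range(10):
    series, truth = ga.simulate_binding_kinetics(params, n_frames=10_000, seed=seed)
    all_series.extend(series)
est = ga.estimate_pair_binding(all_series, area=params.area,
                               n_c=5, burn_in_fraction=0.1)
print(f"planted   P_b = {truth.P_b:.4f}   K = {truth.K:.2f} nm^2")
print(f"estimated P_b = {est.P_b:.4f}   K = {est.K:.2f} +/- {est.sem_K:.2f} nm^2")
```

prints

```
planted   P_b = 0.3333   K = 11.65 nm^2
estimated P_b = 0.3290   K = 11.42 +/- 0.22 nm^2
```

i.e. the contact → event → binding-constant pipeline recovers the planted
two-dimensional binding constant of the synthetic trans pair within one
SEM. The `examples/` directory holds one short script per capability
(binding constants, membrane roughness and correlations, lamellar-period
extraction, fluctuation-gated binding); each prints the numbers it
computes and a line on what they mean.

A thin CLI wraps the same pipelines:

```sh
glycoadhesion binding --seed 1 --out out/          # synthetic defaults
glycoadhesion fluctuations --seed 1 --out out/
glycoadhesion diffraction peaks.txt --out out/
```

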