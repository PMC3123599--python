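# crowdcell

Agent-based Brownian dynamics of biochemical reactions inside a crowded
virtual cell.

Rate constants measured in dilute assays do not transfer directly to the
cytoplasm: macromolecular crowding raises effective concentrations, slows
diffusion, and sterically hinders encounters, while binding to the
cytoskeleton immobilises molecules and co-localised enzymes can channel
metabolites.  `crowdcell` simulates these effects explicitly: individual
molecules perform a rejection-sampled Gaussian random walk through a
spherical model cell crowded by a random cytoskeleton (capsules) and
immobile crowding spheres, and react through collision-based stochastic
channels.  It is aimed at systems-biology modellers who want to connect
*in vitro* rate constants to *in vivo* kinetics.

## The model in brief

* **Diffusion** — per step `Δx_i = √(2 D₀ Δt) ζ_i` with standard-normal ζ;
  steps ending inside an obstacle or outside the membrane are rejected.
  The long-time MSD slope gives the reduced effective coefficient
  `D_eff < D₀` (`⟨r²⟩ = 6 D t` in 3-D).
* **Bimolecular reactions** — a pair of educts within the physical
  collision radius `R = r_i + r_j` reacts with probability
  `P = k_micro Δt / (4π/3 · R³)` per step, where
  `k_micro = k·k_D/(k_D − k)` and `k_D = 4π(r_i+r_j)(D_i+D_j)` is the
  Smoluchowski diffusion limit.  This reproduces the macroscopic
  mass-action rate `k` in well-mixed conditions, independent of Δt.
* **Surface binding** — adsorption in a reaction layer of height
  `κ_ads Δt` over all structures (mobility set to zero), dissociation with
  probability `k_diss Δt`; transient binding reduces long-time diffusion
  proportionally to the unbound fraction `fu`.
* **Crowding corrections** — closed forms connecting the dilute and
  crowded regimes: `f_vol = 1/(1−ε)`, `f_diff = δ/(β + δ(1−β))` with
  `β = k/k_D`, `δ = D_eff/D₀`, the Monte-Carlo accessibility factor
  `f_access`, and `k_eff = f_vol·f_diff·f_access · k`.
* **References** — mass-action ODE steady states and an exact Gillespie
  SSA for the space-free comparison, plus a homogenised-cell transform
  (volume shrunk by `1−ε`, diffusion reset to `δD₀`, `k_micro` pinned).

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
import crowdcell as cc

# the calibrated crowded model cell: 7 um diameter, random cytoskeleton
# cylinders (2.5 um x 35 nm) plus 60 nm crowding spheres, obstacle count
# calibrated so a 2.5 nm tracer sees a 30.5 % excluded volume fraction
geom = cc.default_cell_geometry(seed=2011)

eps = geom.sample_excluded_fraction(probe_radius=0.0025,
                                    n_samples=200_000, seed=1)
fa = geom.sample_access_factor(r_i=0.0025, r_j=0.0025,
                               n_centers=20_000, n_shell=100, seed=2)
res = cc.effective_diffusion(geom, radius=0.0025, D0=1.0, n_tracers=800,
                             t_end=0.05, dt=1e-6, record_every=500,
                             fit_window=(0.008, 0.04), seed=3)
fac = cc.CrowdingFactors(epsilon=eps.fraction, beta=0.1,
                         delta=res["Deff"], f_access=fa.fraction)
print(f"eps = {eps.fraction:.3f}, f_access = {fa.fraction:.3f}, "
      f"D_eff/D0 = {res['Deff']:.3f}")
print(f"f_vol = {fac.f_vol:.2f}, f_diff = {fac.f_diff:.2f}, "
      f"f_eff = {fac.f_eff:.2f}")
```

prints (about two minutes on one CPU):

```
eps = 0.305, f_access = 0.967, D_eff/D0 = 0.737
f_vol = 1.44, f_diff = 0.97, f_eff = 1.34
```

meaning: the obstacles exclude 30.5 % of the cell volume to a 2.5 nm
tracer, which concentrates the reactants (`f_vol = 1.44`); tracers detour
around the obstacles and long-time diffusion drops to 0.74 of its free
value, which at 10 % diffusion limitation costs only 3 % of the rate
(`f_diff = 0.97`); obstacles shade 3 % of the pairwise interaction volume
(`f_access = 0.97`).  Net effect: a bimolecular reaction at `β = 0.1` runs
1.34× faster in this crowded cell than in the dilute assay.

The `examples/` directory has one short script per capability (crowding
factors, effective diffusion, well-mixed equivalence, transient binding,
enzyme channeling), and the `crowdcell` command-line tool exposes volume
sampling, factor evaluation, config-file runs and the preset experiments
(`crowdcell --help`).

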