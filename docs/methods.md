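# Methods

`crowdcell` simulates reaction–diffusion kinetics of individual molecules in
a spherical model cell crowded by explicit, immobile structures.  This note
records the model, the numerical choices, and what the bundled synthetic
worlds do and do not capture.

## The virtual cell

The cell is a closed ball (default diameter 7 µm).  Crowding comes from two
obstacle families generated at random: capsules standing in for cytoskeleton
filaments (default 25,000 × 2.5 µm length × 35 nm diameter) and immobile
spheres standing in for ribosome-scale particles (default 100,000 × 60 nm
diameter).  Obstacle centres are uniform in the cell ball, cylinder
orientations uniform on the unit sphere; obstacles may overlap one another
and may protrude through the membrane, but only in-cell volume counts toward
occupancy.  Because the measured occupancy of such a world depends on the
overlap/protrusion convention, the generator exposes an obstacle-count
multiplier as a calibration knob.  The default multiplier (0.790) was fixed
once by requiring that the Monte-Carlo excluded-volume fraction for a 2.5 nm
tracer equal 30.5 % — the generator's stated operating point.  At that point
the bare (point-probe) occupancy measures ≈ 24 %.  Excluded-volume sampling
draws uniform points over the probe-centre domain (cell radius minus probe
radius), so the reported fraction reflects obstacle crowding rather than the
trivial membrane shell.

Queries use a uniform-grid index.  Every obstacle is registered in all grid
cells whose centre lies within `r_obstacle + reach + h·√3/2` of it
(`h` = grid cell size, default `max(r_max + reach, 2R/140)`; `reach` = 10 nm
is the largest supported probe radius).  A query then inspects only the cell
containing the query point and is guaranteed to see a superset of all
relevant obstacles; tests verify exact agreement with a brute-force scan.

## Diffusion

Each unbound molecule takes an independent Gaussian step per timestep, with
per-axis variance `2·D0·dt`.  A step whose endpoint would overlap an
obstacle or leave the membrane is rejected wholesale; the molecule waits for
the next step.  Mobile molecules do not exclude volume against each other.
Whole-step rejection converges to reflected Brownian motion as `dt → 0`; at
finite `dt` it carries an O(step/feature-size) bias in the effective
diffusion coefficient, which is why the effective-diffusion measurements
below use `dt = 1 µs` (2.2 nm rms axis step against 17.5 nm cylinder radii).

Effective diffusion is estimated from the time-origin-averaged mean squared
displacement, `⟨r²(t)⟩ = 6·D·t` in free space.  In the crowded cell the MSD
slope decays from `D0` (lags shorter than the obstacle spacing) to a reduced
long-time plateau `D_eff`, and at very long lags bends over again as the
closed membrane confines the walk.  The default fit window (8–40 ms for the
7 µm cell) sits past the anomalous transient (crossover ≈ 2–3 ms) and below
noticeable confinement (MSD ≤ 1–2 % of its saturation value).  With this
estimator the calibrated default cell gives `D_eff/D0 ≈ 0.72 ± 0.02` for
2.5 nm tracers.  The reference value for a cell at the same excluded-volume
operating point is 0.77 ± 0.01; the residual offset is attributable to
details of the obstacle placement convention that the excluded fraction
alone does not determine — different microstructures at equal ε give
different `D_eff`.  We report our measured value rather than tuning the
convention further.

## Reactions

The simulator's claim is that it reproduces macroscopic mass-action kinetics
in well-mixed conditions while keeping the collision physics explicit.

**Bimolecular.**  For a channel with macroscopic rate `k_macro` (L mol⁻¹
s⁻¹), the diffusion-limited collision rate is `k_D = 4π(r_i+r_j)(D_i+D_j)`
(converted via N_A/10¹⁵), and the per-collision reactivity follows from
`1/k_macro = 1/k_micro + 1/k_D`, so `k_micro = k_macro·k_D/(k_D −
k_macro)`; requesting `k_macro ≥ k_D` is an error.  Each step, every pair of
educts closer than the physical collision radius `R_crit = r_i + r_j` reacts
with probability `P = k_micro·dt / (4π/3·R_crit³)` — the reaction volume
implied by `k_micro·dt`, expressed as a probability over the collision
volume.  Candidate pairs are visited in uniformly random order and each
particle reacts at most once per step, which makes the serial sweep
equivalent in distribution to any as-if-simultaneous update.  Products
replace educts in place (the first educt's position survives); catalytic
educts — species appearing on both sides — are left untouched.  `P ≤ 1` is
enforced before a run starts; the presets keep `P ≤ 0.1` and, for channels
with `k_macro/k_D ≳ 0.1`, also keep the rms step below `R_crit` so the
depletion zone around reactants is resolved.  Under these bounds the
measured bulk rate in a dilute box is invariant to halving or quartering
`dt` and converges to `k_macro` (tested for `β = k_macro/k_D` in {0.01, 0.1,
0.3}).

**Zero order.**  Molecule creation is Poisson per step with mean
`k₁·(N_A/10¹⁵)·V_cell·dt` (or a direct molecules/s rate), positions uniform
over the accessible placement region by rejection sampling (whole volume or
a membrane-adjacent shell).

**Unimolecular.**  Each educt converts with probability `k·dt`; a warning is
issued when `k·dt > 0.1` (first-order discretisation bias).

**Surface binding.**  Adsorption uses a reaction layer over all structures:
an unbound molecule whose surface-to-surface gap is below `κ_ads·dt` becomes
bound with probability 1 — its position freezes, its species does not
change.  Because positions are equilibrated over the accessible volume, the
resulting bulk binding rate is `κ_ads·A_eff/V_accessible`, where `A_eff` is
the Monte-Carlo-sampled reachable obstacle area; a helper inverts this to
parameterise a target bulk rate.  The layer must stay far below the obstacle
radii (flat-layer assumption; enforced).  Bound molecules dissociate with
probability `k_diss·dt` per step.  The realised steady-state unbound
fraction `fu` follows `k_diss/(k_diss + k_bind,eff)` only approximately:
binding is itself diffusion controlled, so relaxation is not exactly
two-state.  The long-time effective diffusion of a transiently binding
population scales with `fu`.

**Membrane transport.**  Influx is a zero-order source in a membrane shell
(default 50 nm).  Export is a capture layer at the membrane of height one
rms step with capture probability 1 — effectively a near-perfect absorber.

## Well-mixed references and crowding corrections

The enzymatic test model (`0 → S` at `k₁`; `S + E → P + E` at `k₂`;
`c_E = 2·10⁻⁷ mol/L`) has the well-mixed steady state `c_S = k₁/(k₂·c_E)`.
Counts use the enzyme bookkeeping convention: the cell volume is the one
that holds 20,600 enzymes at `c_E` (≈ 171 µm³), which fixes the count convention.  A plain direct-method Gillespie SSA provides the
stochastic well-mixed reference for arbitrary mass-action networks.

In the crowded cell the bimolecular rate shifts by three factors:
`f_vol = 1/(1−ε)` (excluded volume raises effective concentrations, counted
once per bimolecular channel), `f_diff = δ/(β + δ(1−β))` with
`β = k_macro/k_D` and `δ = D_eff/D0` (fixed `k_micro`, `k_D` scaled by δ),
and `f_access`, the Monte-Carlo mean accessible fraction of the pairwise
interaction volume (sampled over accessible centres; partner positions are
scored against obstacles only, so an empty world gives exactly 1).  The
in-vivo steady-state prediction divides the in-vitro one by
`f_eff = f_vol·f_diff·f_access`.

The homogenised-cell transform provides the control: an obstacle-free cell
with volume scaled by `(1−ε)`, particle diffusion reset to `δ·D0`, and
`k_micro` pinned to the in-vitro collision rate.  At `β = 0.3` the detailed
crowded cell reacts measurably *faster* than the `f_eff` prediction based on
the long-time δ, while the homogenised cell does not — the diffusion-limited
reaction senses an intermediary effective diffusion coefficient, between
`D0` and the long-time `D_eff`, because encounters resolve on sub-crossover
length scales.

## Enzyme channeling

The pathway preset is: membrane influx of metabolite 2, three enzymatic
conversions (metabolites 2→5, each `k = 3.78·10⁶ L mol⁻¹ s⁻¹`, enzymes
immobilised at `D = 0`), and membrane export of metabolite 5.  Layouts share
totals, rates and seeds: (A) co-localised ordered stacks just under the
membrane — each stack holds one enzyme of every step, ordered inward at
7.5 nm spacing, an assembly line perpendicular to the membrane; (B) enzymes
uniform in the 50 nm membrane shell; (C) enzymes uniform in the cell volume;
(D) a Gillespie reference with no space at all.  For (D) the export becomes
the bulk analogue of the capture layer, a first-order rate `κ_exp·A/V` —
i.e. (D) keeps the membrane permeability but neglects the diffusion transit,
which is precisely the spatial effect the comparison isolates.

With fixed totals the volume-averaged conversion rate per metabolite is
identical for all layouts; placement matters only while metabolite profiles
remain spatially structured.  The preset scale for the comparisons (cell
radius 2.5 µm, 40,000 enzymes per step, influx 300 s⁻¹) was chosen so the
per-stage conversion time (≈ 0.2 s) is well below the cell mixing time
(≈ 1 s at `D = 1 µm²/s`), making the orderings resolvable above counting
noise within a ~1.6 s simulation; at `D = 10 µm²/s` mixing is fast and the
layout differences shrink, as expected.  Reference values for the influx and enzyme
parameters of the channeling comparison are not available, so only the
orderings — not the curves — are asserted.

## Problem sizes and determinism

Long-run comparisons use reduced volumes at matched concentrations (or
raised concentration scales with `k₁` scaled to preserve the steady-state
count ratio), which leaves `β`, ε and the obstacle microstructure unchanged
while shortening relaxation times; the scaled in-vivo geometry keeps the
obstacle radii and re-calibrates the count multiplier to the same 30.5 %
operating point.  Every stochastic component (generators, samplers, engine,
SSA) takes an explicit seed and is bit-reproducible; observation never
consumes random numbers, so changing the recording schedule cannot change a
trajectory.

Known limitations: no hydrodynamic interactions; no excluded volume among
mobile molecules; isotropic reactivity (no orientation/active-zone effects);
static obstacles only; first-order discretisation of unimolecular channels;
endpoint-only rejection can step across very thin obstacles if `dt` is
chosen too large for the geometry.
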