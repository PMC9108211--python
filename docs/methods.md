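# Methods

`azsim` simulates the calcium microdomain that forms at a single presynaptic
active zone (AZ) of the Drosophila larval neuromuscular junction during
action-potential stimulation, and quantifies how the T-bar — the
table-shaped electron-dense specialization found at a subset of these AZs —
reshapes that microdomain.

## Model

### Geometry

The computational domain is a cuboid of cytosol whose floor is the
presynaptic membrane (default 1.2 × 1.2 × 0.6 μm; a reduced
0.6 × 0.6 × 0.3 μm box is the desk-scale default, see *Domain size* below).
The T-bar is modelled as an impermeable solid: a cylindrical leg (30 nm
diameter, 40 nm tall) carrying a circular roof (140 nm diameter, 10 nm
thick). Three anatomies are compared:

1. **tbar_clustered** — T-bar present, channels clustered in a 70 nm-diameter
   zone around the leg socket (an annulus from the 15 nm leg radius to 35 nm);
2. **no_tbar_clustered** — same channel annulus around a *virtual* socket,
   no obstacle;
3. **no_tbar_dispersed** — no obstacle, the same six channels spread over a
   140 nm-diameter disk.

The clustered zone keeps its annular footprint in the no-T-bar case so that
the two clustered scenarios differ *only* in the obstacle; this isolates the
T-bar's diffusion-barrier effect from the channel-placement effect.

The domain is discretized on a uniform cell-centered Cartesian voxel grid
(default spacing h = 10 nm). A cell is solid exactly when its center lies
inside the analytic T-bar (staircase representation); the spacing must
resolve the roof (h ≤ 10 nm) and tile the box exactly. Floor faces carrying
channel flux are weighted by the fraction of their area inside the analytic
zone (8×8 midpoint subsampling). This weighting matters: with binary
in/out membership the discretized zone edge makes probe readouts oscillate
at the 10⁻³–10⁻² level between refinement levels, masking grid convergence.

### Transport and buffering

Free calcium and a mobile endogenous buffer (calbindin-like) diffuse and
react by mass action:

∂[Ca]/∂t = D_Ca Δ[Ca] − R,  ∂[B]/∂t = D_B Δ[B] − R,
R = k_on [B][Ca] − k_off ([B]_tot − [B]),

with D_Ca = 200 μm²/s, D_B = 30 μm²/s, k_on = 44 /(μM·s), k_off = 36 /s,
[B]_tot = 40 μM. Initial conditions are spatially constant at rest:
[Ca]₀ = 50 nM and [B]₀ = [B]_tot·K_D/([Ca]₀ + K_D) with K_D = k_off/k_on.
Side and top walls hold both species at these resting values (Dirichlet far
field — the bouton is treated as a large reservoir); the floor and the
obstacle surface are no-flux except on the channel zone.

### Membrane flux

On the channel zone the inward flux density (μM·μm/s) is

ρ_VGCC·I_VGCC − ρ_PMCA·I_PMCA − ρ_NCX·I_NCX + leak.

* **VGCC.** N-type channels, single-channel Goldman–Hodgkin–Katz current
  gated Hodgkin–Huxley-style: I = m²h · F_GHK(V, [Ca]ᵢ, [Ca]ₑ) with
  [Ca]ₑ = 1.5 mM, F = 9.648·10⁴ C/mol, R = 8.314 V·C/(K·mol), T = 300 K,
  z = 2. A first-order series branch handles V → 0. Gating follows the
  Borg-Graham rate form (α, β exponential in voltage with partition γ = 0.5,
  τ = τ_min + 1/(α+β)); the shipped N-type preset uses: activation m
  (z = 3.4, V½ = −21 mV, τ_min = 1.5 ms, power 2) and inactivation h
  (z = −2, V½ = −40 mV, τ_min = 75 ms, power 1). The single-channel
  permeability p_x = 3.8·10⁻¹⁹ m³/s gives sub-picoampere single-channel
  currents and peak microdomain concentrations in the tens of μM. The
  scenario comparisons are ratios at matched peaks, so they are insensitive
  to the overall influx scale — only the shape of the waveform and the
  anatomy matter.
* **Channel density.** ρ_VGCC defaults to n_channels / (discretized zone
  area), guaranteeing exactly the same total channel count (6) in every
  scenario. The published density figures (2297.1 and 395.8 μm⁻²) are
  available as a `density_mode="printed"` preset; they correspond to
  slightly different zone areas than the analytic annulus/disk.
* **Pumps.** PMCA: Hill form I_p·c²/(H_p²+c²) with I_p = 8·10⁻²⁴ mol/s,
  H_p = 60 nM, density up to 75 000 μm⁻². NCX: I_x·c/(H_x+c) with
  I_x = 2.5·10⁻²¹ mol/s, H_x = 1.8 μM, density up to 2 500 μm⁻². The NCX
  denominator exponent is configurable separately (some sources print an
  inconsistent exponent); the default is the plain n_x = 1 Hill form.
* **Leak.** A constant inward flux density fixed at calibration time so the
  net membrane flux at rest (V = V_rest, gates equilibrated, [Ca] = 50 nM)
  is exactly zero. With the default maximal pump densities the calibrated
  leak is ≈ 400 μM·μm/s; it balances the pumps, which at rest dominate the
  (nearly closed) channels.

Currents in ampere convert to molar flux via 1/(zF) and 1 mol = 10²¹ μM·μm³.

### Stimulation

A periodic action-potential train (20–100 Hz). Each period contains one
spike: a difference-of-exponentials depolarization from −70 mV to +20 mV
(rise 0.1 ms, decay 0.6 ms) after an onset delay of 3.1 ms within the
period. The delay is part of the waveform template: with the N-type
activation kinetics above it places the first calcium peak at ≈ 4.2 ms
after stimulus onset, the reference timing for peak-matched comparisons.
Calcium influx peaks on the falling flank of the spike (the driving force
grows as the membrane repolarizes while the gates are still open — the
classical tail current). An optional CSV waveform (time, voltage) can
replace the template.

## Numerics

Each time step is an operator split:

1. **Gating** — exact exponential relaxation of each gate at frozen V(t).
2. **Membrane flux** — evaluated per channel face with the face [Ca]
   reconstructed by linear extrapolation from the first two cell layers
   (centers at h/2 and 3h/2). Cell-center sampling alone leaves a
   first-order offset f·h/(2D) in the GHK driving term — at spike voltages
   the local [Ca]ᵢ is tens of μM and this offset measurably pins grid
   convergence at O(h).
3. **Diffusion** — backward Euler, 7-point finite volume, per species, with
   the flux as a Neumann source (flux × weighted face area / cell volume).
4. **Reaction** — exact local solution: Ca − B is conserved under pure
   binding, reducing the two-species kinetics to a constant-coefficient
   Riccati equation solved through its equilibrium roots; positivity and
   B ≤ B_tot are preserved structurally.

**Linear solves.** With Dirichlet sides/top and a Neumann floor the
obstacle-free backward-Euler operator is separable and diagonalized exactly
by fast transforms (DST-II along x and y; DCT-IV along z). Obstacle-free
grids are therefore solved directly at machine precision. With a T-bar, the
obstacle only removes the fluid–solid face couplings, a low-rank
perturbation handled by a Woodbury capacitance correction (one Cholesky
factorization of a k×k matrix per diffusivity/time-step pair, k = number of
interface faces; ~400 at h = 10 nm). For very fine T-bar grids (k > 1500)
the solver falls back to FFT-preconditioned conjugate gradients, and sealed
(all-Neumann) test boxes use diagonally preconditioned CG. Agreement with
the assembled sparse system is asserted at machine precision in the tests.

**Time steps.** dt = 5 μs inside a window around each spike's
depolarization ([delay − 0.5 ms, delay + 3 ms]), 50 μs elsewhere. Backward
Euler with exact gating/reaction substeps is unconditionally stable; the
waveform (0.1 ms rise) is well resolved, and identical stepping across
scenarios cancels the residual first-order time bias in the compared
ratios. A negative concentration after a step (never observed in practice)
triggers step halving with bounded retries rather than clipping, which
would destroy mass conservation.

**Domain size.** The default "reduced" box (0.6 × 0.6 × 0.3 μm) is used for
all quantitative runs; the full printed box (1.2 × 1.2 × 0.6 μm) is a
config switch. Enlarging the box shifts absolute first-peak probe readouts
by only a few percent (the microdomain occupies ≲ 0.1 μm around the channel
zone and the Dirichlet walls act as the bouton reservoir either way), and
the shift is common to all scenarios, so the compared ratios move far less;
the far-field test in the suite checks this. Convergence
studies use a still smaller box (0.16 × 0.16 × 0.08 μm) so that four nested
levels (h = 10 → 1.25 nm) stay desk-scale.

## Readout

Concentrations are quantified on rings of points (default 64) around the
(virtual) socket axis at radius R and height H (raster Δ = 10 nm), averaged
per ring after trilinear interpolation from cell centers; stencil corners
inside the obstacle are dropped and the weights renormalized (flagged in
the output). Rings must clear the socket (R > 15 nm). Peaks are detected
as the maximum within each spike-period window; scenario ratios are formed
at matched per-scenario peak times by default, with a fixed-time variant
available. A volume-averaged readout over the subdomain under the (virtual)
roof (height < 40 nm, radius < 70 nm) complements the rings.

## What the generator emulates — and what it does not

All inputs are synthesized: the anatomies, the kinetic parameter table, and
the stimulation. The model inherits the idealizations of its continuum
formulation: concentrations are ensemble-mean densities (no stochastic
single-channel gating, no discrete-ion noise, although only a handful of
free ions occupy the under-roof volume at rest), channels form a continuum
density rather than discrete puncta, the T-bar is a rigid rotationally
symmetric solid rather than a reconstructed mesh, and there is no
calcium-induced channel inactivation beyond the slow gating variable and no
vesicle-release model. Passing tests therefore validate the *relative*
geometry effects under these assumptions, not absolute microdomain values
in a real bouton.

## Key findings and a known discrepancy

At the first 40 Hz peak the T-bar raises the ring average at R = 30 nm,
H = 10 nm by ≈ 30% over the identical anatomy without the obstacle, and by
≈ 1.9× just under the roof (H = 40 nm); the same pattern recurs at later
peaks and other frequencies, and is insensitive to channel count and to
switching the buffer/pumps off. These match the published ≈ 25% / ≈ 2×
figures.

The ordering T-bar ≥ clustered ≥ dispersed holds at every probe under and
near the roof (R ≤ 50 nm). Beyond the roof edge the dispersed case locally
exceeds the clustered one: probes at R = 60–70 nm sit outside the clustered
annulus but directly over the dispersed source disk.

The published claim that the dispersed-channel case sits a full order of
magnitude (~10×) below the T-bar case is **not** reproduced: this simulator
computes ≈ 2.2× (averaged over R = 30–40 nm, H = 10–40 nm). An independent
quasi-steady Green's-function integral over the two source layouts (same
total influx, zone radii 35 vs 70 nm) predicts a clustered/dispersed ratio
of only ≈ 1.2–1.4 at these probes, i.e. ≈ 2–3× once the obstacle factor is
included — consistent with what the solver computes. A ~10× suppression
would require the probe concentration to scale with the *local* channel
density (ratio ≈ 5.8), which the diffusion equation does not produce at
probe heights (10–40 nm) small compared with the zone radii. The
`acceptance` report states the computed fold.

## Numerical robustness

A 0.5 ms single-pulse convergence study over four nested levels
(h = 10, 5, 2.5, 1.25 nm) shows second-order decrease of probe differences
for the smooth-geometry (dispersed) anatomy, reaching < 10⁻³ between the
finest pair; the staircase T-bar obstacle limits its own case to a
first-order decrease at these spacings (the boundary-fitted alternative is
out of scope by design). Mass conservation in sealed boxes holds to the
linear-solver tolerance; the pure-diffusion solver matches the half-space
Green's-function steady state within 5%, and the gating and reaction
substeps match adaptive ODE integrations to 10⁻⁸ relative error.

## Default problem sizes

Quantitative runs: reduced box at h = 10 nm (108 000 cells), first-peak
runs 6 ms of simulated time, later-peak runs up to 56 ms; convergence
studies on the small box up to 1.05 M cells. These sizes keep every run in
the minutes range on a single CPU core.
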