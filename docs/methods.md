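# Methods

## The model

`minflow` simulates the MinD/MinE reaction cycle on a supported lipid
bilayer coupled to the bulk solution above it, with a uniform lateral bulk
flow. Six species are tracked as areal densities on a laterally periodic
domain (the vertical bulk dimension is integrated out, and the bulk-height
factor is absorbed into the attachment rate constants):

* membrane MinD `m_d` and membrane MinDE complex `m_de`;
* bulk MinD-ADP `c_DD` and MinD-ATP `c_DT`;
* bulk reactive MinE `c_Er` and latent MinE `c_Ei`.

Membrane species diffuse slowly (`D_m`) and are never advected; bulk
species diffuse fast (`D_c`) and are advected at the flow velocity `v_f`
(bulk MinE advection can be switched off independently — the in-silico
ablation). The reactions are mass-action: basal attachment `k_D c_DT`,
self-recruitment `k_dD m_d c_DT`, recruitment of reactive and latent MinE
(`k_dEr`, `k_dEi`), complex detachment `k_de m_de` (releasing MinD-ADP and
reactive MinE), nucleotide exchange `λ` in the bulk, and conformational
switching of reactive to latent MinE at rate `μ`. Both total densities
(MinD, MinE) are conserved exactly; their ratio, the E:D ratio, is the main
control parameter.

Model variants:

* **full** — the six-field switch model above;
* **skeleton** — no conformational switching (`μ = 0`, no latent pool),
  valid at low E:D where most MinE is reactive and rapidly cycling;
* **reduced switch** — the high-E:D limit in which bulk MinE gradients are
  negligible: both MinE pools are spatially uniform and slaved to the
  instantaneous global membrane state through the switching quasi-steady
  state plus MinE mass conservation, leaving `m_d, m_de, c_DD, c_DT` as the
  dynamical fields.

Sign conventions, used everywhere: `+x` is downstream; perturbations are
`exp(iqx + σt)`; the phase velocity of a mode is `−Im σ/q`; a pattern is
*downstream* when its measured velocity has the sign of `v_f` and
*upstream* otherwise.

## Default parameter set (`denk2d`)

The registry ships one default set, `denk2d`, for the same reaction scheme
in the 2D bulk-integrated geometry:

| parameter | value | units | meaning |
|---|---|---|---|
| k_D | 4e-4 | 1/s | basal attachment (bulk areal → membrane) |
| k_dD | 2e-3 | μm²/s | MinD self-recruitment |
| k_dEr | 5.5e-2 | μm²/s | reactive-MinE recruitment |
| k_dEi | 1.4e-3 | μm²/s | latent-MinE recruitment |
| k_de | 0.27 | 1/s | MinDE detachment |
| λ | 0.08 | 1/s | nucleotide exchange |
| μ | 2.8 | 1/s | MinE switching (reactive → latent) |
| D_m | 0.18 | μm²/s | membrane diffusivity |
| D_c | 65 | μm²/s | bulk diffusivity |
| n_D | 2500 | 1/μm² | mean total MinD density |

The rates were fixed by a linear-stability survey of this model family so
that the simulated regime structure matches the in vitro phenomenology
that the package is built to study, at in vitro-like scales:

* low E:D (≲ 0.1): laterally **stable** at rest, but bulk flow opens a
  long-wavelength **downstream**-propagating band (a flow-driven
  instability, growth ∝ flow speed);
* E:D ≈ 0.105: onset of a short-wavelength **oscillatory** instability at
  rest (wavelength ≈ 40–60 μm, phase speed ≈ 0.2–0.6 μm/s, i.e. hundreds
  of nm/s — the in vitro regime);
* E:D ≈ 0.15–0.25: both bands coexist under flow; the developed nonlinear
  wave propagates upstream or downstream depending on flow speed and
  history (multistability, hysteresis);
* E:D ≳ 0.3: the well-mixed kinetics themselves become oscillatory
  (homogeneous Hopf regime); sweeps stay below it by default.

Reproducing this regime structure — rather than any particular printed
rate constants — is what anchors the set; with different microscopic rates
of the same family all qualitative results below are unchanged wherever the
same regime structure exists. Slow nucleotide exchange (λ ≪ 1/s) is what
gives the bulk MinD-ADP pool its role as the delayed reservoir driving the
oscillatory instability; the reactive-MinE pool at these ratios is small
(c_Er* ~ 5–15/μm²) and its local depletion is part of the wave mechanism.

## Numerics

Strang splitting with *exact* spectral transport: diffusion and advection
are linear constant-coefficient operators on a periodic grid, so each half
step multiplies the Fourier modes by `exp(−(D q² + i q v) Δt/2)`; the
pointwise reaction system is advanced with classical RK4. Consequences:

* no numerical diffusion and no CFL restriction from transport; the time
  step is set by reaction stiffness (`dt ≈ 0.01–0.02 s` for the default
  rates);
* the zero mode has multiplier exactly 1 and the reaction fluxes sum to
  zero pointwise, so both total densities are conserved to machine
  precision;
* spectral transport can undershoot slightly below zero where a bulk pool
  is depleted to ~0 by a sharp wave. Undershoots are zeroed and the added
  mass is removed proportionally from the positive part of the same
  species (mass-conserving positivity fix); events are counted on the
  trajectory. Undershoot beyond 1e-4 of the total density aborts the run.
* membrane fronts have width ~√(D_m/k_de) ≈ 0.8 μm, so production grids
  use dx ≈ 1 μm; sweep segments that still blow up are retried with a
  halved step.

The homogeneous steady state is found by relaxing the well-mixed rate
equations from the uniform partition (all MinD as `c_DT`, all MinE as
`c_Er`) and polishing with a Newton solve under both conservation
constraints; when the well-mixed dynamics are oscillatory, Newton is
re-seeded from the cycle average. Uniform states are advection-invariant,
so the result is a fixed point of the full dynamics for any `v_f`.

Linear stability uses the hand-derived reaction Jacobian (cross-checked
against finite differences in the tests) plus the diagonal transport term
`−q²D − iqv` per species; eigenvalue branches are matched between adjacent
wavenumbers by eigenvector overlap. For the reduced-switch variant the
Jacobian is the 4×4 MinD block, defined for q > 0 (zero-mean perturbations
leave the slaved MinE pools untouched); its conservation null space at
q = 0 is one-dimensional, so the two-zero-eigenvalue property is a
full/skeleton statement.

## Measurement conventions

Pattern velocity is the phase drift of the dominant spatial Fourier mode
of `m_d` over the measurement window (least-squares slope of the unwrapped
phase); wavelength is the spectral peak with parabolic interpolation. A
pattern is *present* when the spatial standard deviation of `m_d` exceeds
1% of its mean, and *stationary* when |velocity| is below the resolution
bound dx/T_measure. Sweeps relax for `t_relax` and measure for
`t_measure` at each control value, continuing from the previous final
state (adiabatic protocol); multistability is probed with three initial
conditions per point (noisy homogeneous, downstream-seeded,
upstream-seeded). Default dwell times are chosen as ≥10 wave periods of
the default set (periods are ~60–150 s) and the measured period is logged
with every measurement so adequacy is auditable.

## The reduced-switch direction measurement

With the `denk2d` rates the reduced-switch model is linearly damped at
every wavenumber (the full model's instability at these ratios involves
local reactive-MinE depletion, which the reduction removes by
construction). Its response to flow is therefore measured on *seeded
transients*: a developed full-model wave is handed to the reduced
dynamics and the drift direction of the decaying pattern is measured while
its amplitude remains above threshold. Both this transient drift and the
phase velocity of the least-damped internal eigenmode are upstream at
every tested (E:D, v_f > 0) — the reduced model responds to flow
exclusively upstream, which is the model-discriminating statement the
variant exists to test. The skeleton variant, by contrast, has genuinely
growing flow-driven bands at low E:D and is exclusively downstream.

## Synthetic image stacks

The generator emulates in vitro fluorescence time-lapses: plane waves or
Archimedean spirals with wavelengths of tens of μm and speeds of
100–600 nm/s, sampled at 15 s frame intervals; additive Gaussian noise
with optional Poisson shot noise; mono-exponential bleaching; static
bright Gaussian blobs standing in for protein aggregates; optional
Gaussian blur as a stand-in for the PSF. Frames are quantized to integer
camera counts, so stacks round-trip losslessly through 16-bit TIFF. What
it does **not** emulate: optical sectioning, tile stitching seams,
background gradients, pattern defects and wavefront curvature of real Min
patterns, or aggregate photobleaching. Ground-truth recovery by the crest
analyzer on these stacks therefore validates the estimator's geometry and
statistics, not its robustness to every artifact of real microscopy.

## Crest velocimetry

Phase images are the per-pixel temporal analytic signal after per-frame
bleach normalization (global median to the temporal median), per-pixel
detrending, and a Gaussian band-pass around the dominant temporal
frequency of the stack; pixels whose envelope falls below 20% of the
median envelope are masked, never fabricated. The sign convention makes
the phase of `cos(k·r − ωt)` come out as `k·r − ωt`, so the phase gradient
points along the propagation direction. Crests are the sub-pixel zero-phase
level set (`sin φ = 0` intersected with `cos φ > 0`). Each crest point is
translated to the next frame by matching an intensity profile along the
local wave normal within ±λ/4, maximizing normalized correlation with
parabolic sub-pixel refinement; matches with correlation < 0.3 or at the
search boundary are dropped and counted. Velocities are reported in nm/s.
Records with speed below 10% of the median speed are removed (static
aggregates), and the direction statistics use 25 nm/s 2D bins, 15°
half-open angular segments (a−15°, a], a downstream segment (−30°, 30°],
an upstream segment (150°, 210°], and a peak speed ± FWHM/2 from a
10 nm/s speed histogram.

## The shipped verification protocols

`minflow.protocols` packages the computational experiments that back the
test suite and the reproduction script; design choices worth knowing:

* **Upstream onset** (`upstream_onset_sweep`): an adiabatic E:D loop at
  v_f = 2 μm/s, a few times the intrinsic wave phase speed. The upward
  leg from E:D = 0.02 develops a downstream wave on the march and —
  because of multistability — carries it to the top ratio; the downward
  leg starts from a seeded band-peak-wavelength upstream wave at the top
  ratio (the upstream member of the multistable pair) and carries it
  down until it converts to the flow-driven downstream state. The
  reported onset is the smallest ratio classified upstream anywhere on
  the loop: the existence boundary of upstream propagation at this
  flow. The flow speed matters: at much weaker flow finite-amplitude
  upstream waves are deeply subcritical and persist to arbitrarily small
  ratios (no boundary is measurable), while at a few μm/s the
  flow-driven downstream band is strong enough to take over at a
  well-defined, seed-robust ratio. The upward leg doubles as the
  hysteresis exhibit (downstream at ratios where the downward leg
  sustains upstream waves).
* **Flow-driven threshold** (`flow_driven_report`): stated on the
  discrete mode spectrum q = 2πk/L of a 512 μm domain. On the infinite
  domain the conserved modes are soft (Re σ → 0⁻ as q → 0) and the
  threshold degenerates to ~0; any realizable geometry admits only
  q ≥ 2π/L, giving a finite threshold (≈ 0.1 μm/s at E:D = 0.05)
  confirmed by eigenmode-seeded simulations on both sides.
* **Flow hysteresis** (`hysteresis_report`): a signed flow loop at
  E:D = 0.2 — up from +0.5 to +7 μm/s, back down and through zero to
  −7 μm/s, mirroring the flow-reversal experiment. Both propagation
  senses are stable over a broad range, so the two dynamical reversals
  (sign changes of the measured lab-frame velocity) occur at different
  control values, and in the overlap the direction at a given flow
  depends on sweep history.
* **Variant grids**: the skeleton variant is probed at low ratios
  (E:D 0.02–0.05) with seeded long-wavelength waves (its flow-driven
  band); the reduced-switch variant at E:D 0.15–0.3 via the seeded
  transient-drift measurement described above.
* **Coarsening** (`coarsening_report`): from noise at E:D = 0.12,
  v_f = 1 μm/s on a 256 μm domain — just below the upstream onset, where
  the pattern starts as a ~50 μm downstream train and coarsens through
  pulse mergers into a single domain-spanning pulse. At much lower
  ratios the flow-driven band already peaks near the domain scale and
  the single pulse forms directly, with no visible coarsening sequence.

## Problem sizes

The protocols run on desk-scale versions of the production geometry: 1D
domains of 256–512 μm at dx = 1 μm, dt = 0.01 s (segments that blow up
retry at dt/2), sweep dwell times of a few hundred seconds per control
value, and image stacks of ~128–160 px and 24–30 frames. These sizes were
chosen so the full verification suite runs on a laptop-class single core;
the grid-refinement invariant (pattern wavelength and speed change < 2%
upon doubling N) is what justifies trusting them.

## Known limitations

* The kinetic rates are family-calibrated, not fitted to any measured
  dataset; quantitative observables (exact onset ratios, wave speeds)
  depend on them.
* The 2D bulk reduction discards vertical bulk gradients; the skeleton
  variant's validity at low E:D and the reduced variant's at high E:D are
  regime statements, not uniform approximations.
* No Poiseuille profile: the bulk flow is uniform, so comparisons with
  channel experiments are qualitative.
* 2D lateral simulations are supported for wave-front alignment
  demonstrations, but all shipped protocols are 1D.
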