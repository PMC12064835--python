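# Methods

This note documents the model, its parameters, the numerics, the
synthetic-data generators, and the design choices made where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The continuum model

We describe the expanding skull-cap tissue on its medial–lateral axis
(+x = medial, the direction of expansion; the bone occupies low x) as a 1D
viscous fluid of two cell populations, undifferentiated mesenchyme (ρ_m)
and osteoblasts (ρ_o), with total density ρ and osteoblast fraction
φ = ρ_o/ρ (defined as 0 where ρ = 0). Three material fields ride with the
flow: the net division rate k, the matrix maturity col ∈ [0, 1], and the
growth pressure P_g.

Population balance:

    ∂t ρ_m + ∂x(ρ_m v) = D ∂x²ρ_m + k ρ_m − λ ρ_m
    ∂t ρ_o + ∂x(ρ_o v) = D ∂x²ρ_o + k ρ_o + λ ρ_m

Differentiation (the λ terms) conserves cell number exactly; only the net
growth term k ρ changes it.

Net growth relaxes toward a density-dependent target,

    ∂t k + v ∂x k = −(k − k*)/τ,   k* = α (1 − ρ/ρ0(col)),

with the homeostatic packing ρ0 rising linearly from ρ0_m to ρ0_o as the
matrix matures (fresh converts still pack like mesenchyme; the bone center
is ~1.5× more densely packed). α is the relaxation rate of the 1D-projected
density; it subsumes both net proliferation and the out-of-plane
accommodation of crowding that a 1D projection cannot represent explicitly
(see Limitations), which is why its default (0.28/h) is much faster than a
cell-cycle rate.

Matrix maturation: osteoblasts deposit and crosslink collagen,

    ∂t col + v ∂x col = r_col φ (1 − col),

and the accumulated matrix — not the instantaneous composition — carries
the mechanical identity of the tissue: stiffness
E(col) = E_m + (E_o − E_m) col (the measured stiffness gradient coincides
with the fibrillar-collagen gradient) and anchoring friction
ξ(col) = ξ [1 + (ξ_ratio − 1) col] (bone-center nuclei are nearly immobile
in live imaging; osteoblasts adhere to the meshwork they secrete). The
composition-slaved closure E(φ) is kept as `stiffness_of_phi` — the two
coincide wherever maturity has caught up with composition, in particular at
both homogeneous homeostatic fixed points.

Mechanics: Stokes flow with friction against the dermal/meningeal layers,

    η v″ − ξ(col) v = ∂x(P_el + P_g),   v(0) = v(L) = 0,

with the elastic crowding pressure P_el = E(φ)(ρ − ρ0(φ))/ρ0(φ) (zero at
homeostasis, rising with over-crowding) and a growth pressure generated by
active matrix deposition,

    ∂t P_g + v ∂x P_g = π0 (E_o − E_m) r_col φ (1 − col) − P_g/τ_P.

Freshly secreted, hydrated osteoid adds volume; mature bone (col = 1) and
cell-free mesenchyme (φ = 0) generate nothing, and stored pressure relaxes
viscoelastically over τ_P. The engine of expansion is therefore the
distributed maturation zone behind the osteogenic front — which is exactly
what a bone-center excision removes.

Differentiation is mechanosensitive:

    λ = β clamp((E_s − E_m)/(E_o − E_m), 0, 1),
    E_s = E(col) + (E_o − E_m) (χ max(P_el, 0)/E(col))².

Cells read their compressive *strain* max(P_el, 0)/E(col), and collagen
networks strain-stiffen superlinearly, so the same push stiffens a soft,
poorly crosslinked matrix much more than a mature one. This closes the
loop: differentiation → deposition → push → compression of the tissue
ahead → higher sensed stiffness → faster differentiation. It also fixes the
direction of the crosslink-inhibition experiment: softening the fresh
tissue amplifies the strain response, so the treated wave differentiates
and moves faster and leaves a shallower maturity gradient.

Both homogeneous homeostatic states (pure mesenchyme at ρ0_m with col = 0,
pure mature bone at ρ0_o with col = 1) are exact fixed points of the full
system.

## Parameters

Defaults live in `src/osteowave/data/default_params.yaml` (not in code).
Units: stiffness kPa, densities cells/µm (1D-projected), viscosity kPa·h,
friction kPa·h/µm², diffusion µm²/h, rates 1/h, lengths µm, times h.

| name | default | meaning |
|---|---|---|
| E_m, E_o | 1, 3 | mesenchyme / mature-bone stiffness (center ≈ 3× stiffer than mesenchyme) |
| rho0_m, rho0_o | 0.10, 0.15 | homeostatic packing (bone ≈ 1.5× denser) |
| eta | 10 | tissue viscosity |
| xi, xi_ratio | 0.0058, 9.5 | mesenchyme friction; anchoring amplification of matrix-rich tissue |
| D | 1.7 | cell diffusion constant |
| tau, alpha | 0.95, 0.28 | division-rate relaxation time; density-relaxation rate (incl. out-of-plane accommodation) |
| beta | 0.24 | differentiation–stiffness coupling — the single fitted parameter |
| r_col | 0.0032 | matrix maturation rate (1/r_col ≈ 13 days: osteoid → stiff crosslinked bone) |
| pi0, tau_P | 280, 1.7 | deposition-pressure amplitude (scale π0·ΔE·r_col·τ_P ≈ 3 kPa) and its relaxation time |
| chi | 4.3 | strain-mechanosensing gain |
| domain, grid | 1000 µm, 501 pts | 2 µm spacing; the wave stays >100 µm from the walls (asserted at run time) |
| dt, t_end | 0.1 h cap, 48 h | explicit step (clamped to the stability bound) and horizon |

The stiffness and packing ratios and the diffusion constant are set by the
tissue measurements they represent; η, ξ, ξ_ratio, τ, α, r_col, π0, τ_P and
χ were calibrated jointly, by scored search over simulations, so that the
default model reproduces the full set of observed behaviours at once: a
front advancing ≈ 15 µm per 6 h at a steady rate with a shape-preserving
profile, the velocity peak at the osteogenic front, tracked cells reaching
only ~0.7 of the front displacement in 6 h, near-arrest (≤ 20% of control)
after bone-center excision, and faster expansion with a larger final bone
and a shallower front-intensity slope under crosslink inhibition. β's
default is the value a self-consistent fit recovers; it is re-estimated by
`fit_beta` whenever observations are supplied.

## Numerics

Node-centred uniform grid; conservative flux-form advection for the
densities with van Leer (MUSCL) slope limiting — second-order where the
solution is smooth, positivity-preserving, and free of the first-order
upwind's numerical diffusion, which at dx = 2 µm would rival the physical
D and distort the front; first-order upwind advection for the non-conserved
material fields (k, col, P_g); centred diffusion with no-flux boundaries;
the tridiagonal force balance solved with a banded LAPACK factorisation
every step. Explicit Euler stepping with the step clamped to
0.4·min(dx/2max|v|, dx²/2D, 1/rates) — the extra factor 2 on the advective
limit keeps the limited reconstruction positivity-preserving under forward
Euler. A field that becomes negative beyond rounding (−10⁻¹² relative) or
non-finite raises an error naming the field. With growth off, the flux-form
operators conserve total cell number to better than 10⁻⁸ over 1000 steps;
the default speed changes by < 0.5% under 4× grid-and-step refinement.

The `step` preset smooths the φ step over a 10 µm tanh, gives the matrix a
120 µm maturation lag behind the front (the freshly differentiated front
zone is collagen-poor — the bone front is measurably softer than the
center) and primes P_g at its local quasi-steady value, so runs start near
the travelling wave instead of spending ~1/r_col rebuilding its structure.
The `matured-step` preset (sharp front, col = φ) is the fully equilibrated
bone: with β = 0 it is exactly stationary up to diffusive smoothing, the
model's statement that without differentiation there is no expansion.

## Wave analysis and quantification conventions

- The osteogenic front is the medial-most φ = 1/2 crossing, scanned from
  the bone side and linearly interpolated; front speed is the least-squares
  slope after discarding the first half of the record (wave-formation
  transient).
- Tracers are material points of the flow plus Brownian motion with the
  cell D (Euler–Maruyama, reflecting walls, seed-reproducible); the
  relative-displacement comparison normalises both front and mean-cell
  displacement by the front displacement at 6 h.
- MSD uses the displacement-from-origin definition
  (1/N) Σ |x_i(T) − x_i(0)|², not time-lag averaging, and per-track mean
  velocity |x_i(T) − x_i(0)|/T, matching the imaging quantification; track
  velocities for the spatial correlation C_vv are centred differences at
  interior frames (one-sided at the ends), normalised to unit vectors,
  binned by transverse (y) separation.
- Division angles are plain circular data by default (the reported
  statistic is a mean angle near 90°); axial doubling sits behind a flag.
  The Rayleigh statistic is z = nR² with the standard approximation for p.
- Intensity profiles are aligned where they first exceed 1.1× their
  mesenchymal baseline, scanning from the mesenchyme toward the bone; on
  discrete noisy data "first exceeds" is implemented as the first
  exceedance sustained for 3 consecutive samples toward the bone, which is
  identical on noise-free profiles and immune to isolated baseline spikes.
  Aligned distances are positive into the bone, binned at 1 µm within each
  sample and then averaged across samples; the front slope is the
  least-squares fit over 0–100 µm.
- Bone areas use a common intensity threshold and the largest 8-connected
  component; regional proliferation uses the three standard 100 µm windows
  (ahead of the front, behind it, bone center).
- The excision scenario evolves the wave for 24 h and then crops the tissue
  to the leading 20 µm band — genuinely partially differentiated,
  collagen-poor tissue in the developed state — refilling the removed
  region with homeostatic mesenchyme; with the band as wide as the domain
  it reproduces the control exactly. The crosslink-inhibition scenario
  multiplies E_m by 0.5 and E_o by 1.1 and compares speed, final φ ≥ 1/2
  domain size, and aligned front-intensity slopes of reporter profiles
  synthesized from the matrix-maturity field at imaging resolution (1 µm)
  with multiplicative log-normal noise.

## Synthetic data: what it does and does not emulate

The generators reproduce the *statistical structure* the analyses assume:
persistent random walks whose persistence time and medial drift fall from
front to bone center (cohort sizes 199/117/139, 10-min frames, 6 h
sessions); travelling sigmoidal intensity profiles with per-sample
alignment jitter and multiplicative (fluorescence-like) log-normal noise;
von Mises division angles about 90° with a medial daughter-displacement
bias; bright elliptical bone blobs with additive noise and known pixel
areas. Every generator is a pure function of its spec and seed.

They do not emulate nucleus-level image formation, segmentation or
tracking errors, curved or branched real bone fronts, sample-to-sample
biological variability beyond simple offsets, or 3D projection artefacts.
Passing tests therefore demonstrate that the measurement procedures are
correct and that generating parameters are recoverable at realistic noise,
not that the procedures are robust to every pathology of real microscopy.

## Fitting

`fit_beta` minimises the equally weighted sum of squared residuals of the
front and mean tracked-cell displacement curves over a 6 h observation
window of the developed wave, by a bracketing grid plus bounded scalar
minimisation; tracer noise uses common random numbers across evaluations,
making the fit deterministic given the seed. The default residuals are
absolute displacements in µm — the expansion velocities are the fitted
observable — because the front-normalised curves alone
identify the coupling only weakly; they remain available via
`relative=True`. Observations sampled at the 10-min imaging frame rate
from the settled wave recover the coupling exactly without noise and to
within ~10% under 5% per-point multiplicative noise.

## Problem sizes

The shipped configuration — 501 grid points, 48 h horizon, 100–2000
tracers, cohorts of a few hundred tracks, 20 measurement replicates for
scenario contrasts, and ~30 simulations per fit — was chosen so that every
analysis completes in seconds on one CPU while keeping all quantities well
inside their statistical tolerances; the full test suite and the
acceptance script each run in a few minutes.

## Known limitations

- 1D projection: transverse flows, front curvature and out-of-plane tissue
  thickening are collapsed into effective parameters (most visibly α; see
  above). Front-roughness analysis (`front_fluctuations`, the RMS width of
  a transversely resolved front and its log–log growth slope) therefore
  consumes externally supplied front lines rather than model output.
- The closures are minimal: linear stiffness and packing mixing, a single
  maturity field standing in for the osteoid → woven bone → mineralising
  matrix sequence, a quadratic strain-stiffening law with one gain, and a
  single relaxing growth-pressure field. Each closure sits behind its own
  function so alternatives can be swapped.
- The wave's engine zone keeps elongating on the slow maturation timescale
  (1/r_col ≫ the 48 h horizon), so the model is quasi-steady on imaging
  timescales rather than a strict travelling wave; the φ front nevertheless
  translates shape-preservingly (collapse RMS ≈ 0.014).
- With β = 0 a *developing* bone (immature matrix) still pushes residually
  until its deposition engine exhausts; only the fully matured preset is
  exactly inert. The model statement "no differentiation → no expansion"
  holds for equilibrated tissue and over maturation timescales, not
  instantaneously for tissue caught mid-development.
- Hypothesis tests on measured contrasts (Welch, Mann–Whitney, Wilcoxon,
  Rayleigh beyond the z approximation) are delegated to standard
  statistical libraries at report time.
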