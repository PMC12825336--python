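# Methods

`dexdrop` models the formation of water-in-water (ATPS) droplets inside a
dehydrating microfluidic channel, and provides the measurement pipeline used
to quantify the resulting droplet populations. This note records the model,
its assumptions, the numerical choices, and what the synthetic-data tests do
and do not demonstrate.

## Physical model

**Order parameter.** The local state of the PEG/dextran solution is reduced
to a single conserved field η(x, z) ∈ [0, 1], the dextran fraction of total
polymer (η = 0 pure PEG, η = 1 pure dextran). The channel is treated in 2D:
x runs along the channel (periodic boundary), z across it (solid walls).

**Free energy.** The bulk free-energy density is a symmetric
regular-solution form,

    f(η) = RT [η ln η + (1−η) ln(1−η)] + L η(1−η),

plus a square-gradient interfacial term (α/2)|∇η|². The ideal-mixing entropy
term is required for bounded, bistable dynamics: an interaction-plus-gradient
energy alone is quadratic in η and produces unbounded linear growth with no
equilibrium droplets. Demixing occurs for L > 2RT; the curvature
f''(η) = RT(1/η + 1/(1−η)) − 2L defines the spinodal.

**Dehydration as a deepening quench.** Water absorption by the channel walls
concentrates both polymers, which is modelled as a time ramp of the
interaction parameter

    L(t) = L0 + a (1 − 10^(−b t)),

with L0 = 7300 J mol⁻¹, a = 10⁴ J mol⁻¹, b = 5×10⁻³ s⁻¹. At the initial
composition η₀ = 0.38 the system is already weakly inside the spinodal at L0
(f'' ≈ −4.2 kJ mol⁻¹) and deeply quenched at L0 + a (f'' ≈ −24 kJ mol⁻¹).

**Dynamics.** Conserved Cahn–Hilliard dynamics

    ∂η/∂t = ∇·(Mc ∇μ),   μ = δF/δη = RT ln(η/(1−η)) + L(1−2η) − α∇²η,

with constant mobility Mc = D0/RT (D0 = 10⁻¹⁴ m² s⁻¹, R = 8.31 J mol⁻¹ K⁻¹,
T = 295 K) and α = 3.5×10⁻⁸ J m² mol⁻¹. L, a, α are molar energies so that
Mc = D0/RT yields dimensionally consistent fluxes; internally all lengths
are micrometres (D0 = 10⁻² µm² s⁻¹, α = 3.5×10⁴ J µm² mol⁻¹).

**Wall affinity.** The channel surface prefers the PEG-rich phase. Each step,
the outermost fluid layers relax towards η⁰ = 0.4 with first-order kinetics
(rate k = 10⁻⁵ s⁻¹, interpreted per second), and the adjacent layer is
decremented by the identical amount, so every column's mass is conserved
exactly. The relaxation is applied at both walls, after the Cahn–Hilliard
update of each macro step (operator splitting; the commutation error is
O(k·dt) ≈ 10⁻⁵ per step and far below the discretization error).

**Observation clock.** Microscopy begins minutes after the solution is mixed
and loaded, so observation time is Δt = (step − 800)·dt: the printed
snapshot times Δt = 2, 5, 15, 30 min correspond to steps 920, 1100, 1700,
2600 at dt = 1 s.

## Numerics

- **Grid:** 5-point Laplacian, dx = 1 µm, default 256 × 20 cells
  (the channel cross-section is 20 µm; the 256 µm segment length is the
  package's choice — long enough to host ~10 droplets of channel-width
  scale).
- **Boundaries:** periodic in x; mirror ghost cells in z for both η and μ
  (zero flux for both fields — required for exact conservation).
- **Initial condition:** uniform η₀ = 0.38 plus seeded, mean-subtracted
  uniform noise of amplitude 10⁻³. A perfectly homogeneous state cannot break
  translation symmetry under deterministic dynamics; the seeded noise stands
  in for thermal fluctuations and makes every run bit-reproducible. The mean
  is exactly η₀ for any seed.
- **Time stepping:** explicit conservative Euler, flux-difference form.
  The nominal dt = 1 s exceeds the rigorous explicit bound
  dt ≤ 2 / (Mc q²max (f''max + α q²max)) ≈ 0.02 s (q²max = 8/dx²; f''max is
  the entropy curvature at the coexistence composition of the fully
  quenched well, η ≈ 8.7×10⁻⁴). Each macro step is therefore divided into an
  integer number of sub-steps (63 at the default parameters, safety factor
  0.8). `stability_check` reports both bounds and the sub-step count.
- **Logarithm guard and overshoot.** η is clipped to [ε, 1−ε], ε = 10⁻⁶,
  only inside the logarithms (a C⁰ extension of f'); the evolved field is
  never clamped, which preserves exact mass conservation (measured relative
  drift over the full 2600-step run: ~10⁻¹⁶). The discrete solution carries
  a persistent Gibbs overshoot of ~2×10⁻³ above η = 1 in the cells adjacent
  to the (one-to-two-cell wide) interfaces — a spatial discretization
  artifact of the deep quench at dx = 1 µm, not a stability failure. A run
  aborts only if η leaves [−0.01, 1.01] (`overshoot_tol`).
- **Degenerate inputs:** uniform fields are exact fixed points of the CH
  step; empty segmentations return empty sets; zero-variance samples give
  σ = 0 with a degeneracy flag.

## Phase diagram and dehydration timing

The binodal is the standard three-parameter empirical form
c_dex = A exp(B √c_peg − C c_peg³) (% w/v), with default coefficients fitted
exactly through (1, 9.6), (4.8, 4.8), (8, 1.8). The anchors were chosen
once, on two constraints the curve must honor — a 4%:4% mixture is
homogeneous and a 5%:5% mixture is two-phase — with the diagonal crossing
placed at 4.8% (the midpoint constraint interval is (4, 5)) and end points
giving a plausible PEG-8k/DEX-200k-scale curve over the fitted 1–10% range.
No tie-lines or partition coefficients are predicted: classification only.

Dehydration concentrates a composition along the ray c0/(1−φ). The
water-loss fraction φ(t) follows one of two families, φ = min(0.99, c·t/w²)
(quadratic, default) or φ = φmax(1 − exp(−c·t/w²)) (exponential), both with
the 1/width² sensitivity of a diffusion-limited volume-per-wall-area
balance. The single rate coefficient c is calibrated to the four reference
onset observations (5/10/15/20 µm channels at 1–4% w/v, onsets ≈3/7/8/10
min) by least squares on log onset times, so minute-scale and
ten-minute-scale conditions weight comparably; the quadratic fit has the
closed form ln c = mean[ln(φ*ᵢ wᵢ²/tᵢ)].

## Droplet morphometrics

DEX-rich droplets are connected components (8-connectivity) of η > 0.5 — the
midpoint of the two bulk phases — or of intensity above threshold in images.
Components below `min_area` (default 2 µm²) are discarded as pixel noise;
components touching the walls or non-periodic edges are flagged and excluded
from summary statistics by default (partial objects bias the diameter).
On the periodic simulation axis, components adjacent across the seam are
merged (union-find) and their x centroid is the circular mean. The reported
diameter is always the 2D equivalent-circle diameter 2√(area/π); the SD uses
the n−1 denominator, CV = 100·SD/mean. Satellite filtering retains droplets
at or above a diameter cutoff (14 µm for the 20 µm channel population).
Throughput extrapolation is exact arithmetic: linear density × 10⁴ µm cm⁻¹,
times channels per cm. Encapsulation efficiency is the fraction of droplets
containing ≥1 particle, by exact point-in-component lookup when a label
image exists, else by point-in-disk around each centroid.

## Synthetic data: what it emulates and what it does not

The generator renders single-file bright disks in a dark channel — diameters
from a normal distribution truncated to (0, channel width], optional
satellite sub-population, jittered gaps, Gaussian PSF blur (σ = 0.3 µm
default) and additive Gaussian noise — fully seeded. Presets mirror the four
measured populations (widths 5/10/15/20 µm, mean diameters
4.6/9.3/14.1/18.3 µm, CVs 9.8/14.6/12.1/16.3%). Note the preset mean/SD are
the *pre-truncation* normal parameters; at the 20 µm width the truncation at
the channel width shifts the realized mean down noticeably, so round-trip
tests compare segmentation output against the realized ground-truth sample,
which is the honest measure of the measurement pipeline. Passing these tests
shows the segmentation and statistics are unbiased at the study's size and
noise scales; it says nothing about optical effects the generator omits
(photobleaching, flow blur, out-of-focus light, uneven illumination) or
about real microscopy backgrounds.

Field fixtures (tanh-profile disks, interface width 2 dx, η 0.9/0.3) provide
solver-free inputs shaped like late-stage simulation snapshots.

## Problem sizes

The default test and acceptance runs use the full study simulation
(256 × 20 cells, 2600 macro steps ≈ 1.6×10⁵ sub-steps, ~40 s), four
140-droplet synthetic images at 0.2 µm px⁻¹, and 10⁴ droplets for the
Poisson encapsulation check.

## Known limitations

1. **No stationary arrest by 30 min.** At the exact study parameters the
   simulated droplet array is still coarsening between Δt = 15 and 30 min:
   droplet counts drop from ~32 to ~26 (seed-dependent, 3–9 droplets per 900
   steps), approaching arrest only around step 3300+. The qualitative
   picture — a confined array of droplets no wider than the channel — is
   reproduced (max equivalent diameter ~15–16 µm < 20 µm), but the claim of
   a count-stationary array over the 15–30 min window is not. The
   corresponding acceptance test is kept red rather than weakened.
2. **Onset-time ordering.** For symmetric c:c compositions every dilution
   ray crosses the binodal at the same diagonal point x* ∈ (4, 5). Any
   monotone water-loss law φ(t/w²) then predicts the 20 µm/4% channel to
   phase-separate *before* the 15 µm/3% one (preserving the observed
   ordering would require x* ≥ 6.37, incompatible with 5%:5% being
   two-phase). The calibrated quadratic model predicts onsets of
   ≈2.5/7.4/10.7/8.5 min against observed 3/7/8/10 — all within ±50%, with
   the last pair swapped. The ordering test is kept red; resolving it would
   need per-condition physics (e.g. composition-dependent permeability)
   outside this model's scope.
3. 2D only; no hydrodynamic flow coupling; constant (non-degenerate)
   mobility; no inter-channel vapor competition; no humidity or temperature
   dependence of the binodal or of the dehydration rate.
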