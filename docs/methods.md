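# Methods

## Model overview

`geudplan` optimizes the particle numbers N_j of all pencil-beam spots of
all fields simultaneously (multiple-field optimization). The physics is
condensed into a sparse dose-influence matrix d_ij (Gy per particle from
spot j to voxel i), so the physical dose is linear, D_phys = d N. All
doses are per fraction, in Gy.

### RBE-weighted dose (low-dose mixed-field approximation)

Per-spot radiosensitivity tables α_ij and √β_ij, aligned with the
sparsity of d, describe the local linear-quadratic response of the
tissue in voxel i to the radiation arriving from spot j. The mixed-field
coefficients of a voxel are the dose-weighted means

    ᾱ_i = Σ_j d_ij N_j α_ij / D_i,   √β̄_i = Σ_j d_ij N_j √β_ij / D_i

(the Zaider–Rossi mixing rule; note that √β, not β, is averaged). Voxels
with zero dose get ᾱ = β̄ = 0 by convention and never enter an objective.
The biological effect is LQ up to the threshold dose D_t and linear with
slope s_max above it:

    −ln S = (β̄ D + ᾱ) D                 for D ≤ D_t
    −ln S = (β̄ D_t + ᾱ) D_t + (D − D_t) s_max   otherwise

and the RBE-weighted dose inverts the *photon* response (α_x, β_x) at
that effect. With photon-equivalent tables (α_ij = α_x, √β_ij = √β_x)
the construction collapses to D_bio ≡ D_phys on both branches — an
identity the test suite checks to 1e-10 and a useful end-to-end
diagnostic of the whole chain.

Because the effect below D_t has the closed form
−ln S_i = (Σ_j d_ij N_j √β_ij)² + Σ_j d_ij N_j α_ij, the gradient
∂D_bio,i/∂N_j is analytic (quotient rule on the above-threshold branch,
then the derivative of the photon inversion). The ∇RBE contribution is
therefore *not* neglected in the search direction. Gradients are
validated against central finite differences to better than 1e-5
relative error on random instances spanning both branches.

The Monte-Carlo ("classical") effect computation is intentionally not
implemented; the low-dose approximation is the package's single
biological model.

### Objectives

Quadratic penalties normalized by Δ = 0.025 × prescription (half of an
assumed 5% dose-computation accuracy): a two-sided uniform-dose target
term; one-sided max-dose and gEUD terms per OAR (strict inequality: a
voxel exactly at D_max, or an OAR exactly at gEUD₀, contributes zero);
optionally a two-term target gEUD pair (a_min < 0 for cold spots,
a_max > 0 for hot spots) replacing the uniform term. A VOI may carry a
max-dose and a gEUD objective simultaneously; voxels belonging to two
VOIs contribute to both terms (the sums are independent). gEUD and its
dose derivative (D_i/gEUD)^(a−1)/M are evaluated in log space with
max-factoring so exponents like a = 20 neither overflow nor lose the
gradient of zero-dose voxels (defined by continuity: 0 for a > 1, 1/M
for a = 1).

### Optimizer

Line search N_{k+1} = clamp(N_k + μ_k h_k, N_min):

- Directions: steepest descent, or Fletcher–Reeves conjugate gradients
  (β = ‖g_{k+1}‖²/‖g_k‖²) restarted at k = 0, every 25 iterations, after
  a rejected step, and whenever the combined direction fails the descent
  test. The 25-iteration period is a conventional n-independent choice;
  the restart-on-non-descent rule is what actually guarantees progress.
- Stepsize, physical dose: the one-sided active sets are frozen at
  μ = 0, each active gEUD term is linearized along the direction using
  its exact directional derivative, and the resulting quadratic-in-μ
  cost is minimized in closed form (μ = Σ c·r·s / Σ c·s²). This is exact
  for pure voxel-dose plans and gEUD terms with a = 1; for a > 1 it is a
  linearization (`linearized` mode, the default; `analytic` is the same
  computation, named for the exact case). A purely numerical
  `backtracking` Armijo search is provided as an alternative.
- Stepsize, biological dose: the same closed form evaluated at the
  current *biological* dose with the analytic RBE-weighted gradient as
  the linearized slope, then damped by a factor f (default 0.5) to
  absorb the RBE curvature. An earlier variant that solved the stepsize
  on a physical-dose surrogate of the plan stalls immediately after
  preoptimization (the physical target dose already equals the
  prescription, so the surrogate's step is zero while the biological
  cost is far from optimal); linearizing around the biological dose
  fixes this while keeping the damped-step structure.
- Safeguard: if the cost does not decrease at the proposed μ (a
  Heaviside crossing, an overshot linearization, or RBE curvature), μ is
  halved up to 20 times; a still-failing step is rejected and forces a
  CG restart; five consecutive rejections abort. Accepted iterations
  therefore form a strictly decreasing cost sequence — the contract the
  tests enforce.
- Start: uniform spot weights scaled so the mean physical target dose
  equals the prescription (for a target-gEUD plan, the midpoint of the
  min/max prescriptions). Deterministic and adequate; no per-spot
  preweighting is attempted.
- Convergence: relative cost change below rel_tol (default 1e-5) on
  three consecutive accepted iterations, or max_iter (default 500).
  N_min defaults to 0 (continuous relaxation); a scanner's minimum spot
  weight can be imposed by projection through the config.

### Plan evaluation

Cumulative DVHs (default bin width 0.5% of prescription), gEUD at the
configured exponent, conformity index (volume of the 95% isodose over
target volume), EQD2 = D_tot (α/β + d)/(α/β + 2), and LKB NTCP
Φ((gEUD − TD50)/(m·TD50)) with the parotid defaults TD50 = 39.9 Gy
(95% CI 37.3–42.8), m = 0.40 (0.34–0.51); NTCP error bars come from the
CI corners.

Two EQD2 conventions are provided. Read literally, the fractionation
factor uses the structure's own per-fraction dose D_tot/N_frac
(`literal` mode). The default (`prescribed_fraction`) uses the plan's
prescribed fraction dose (3 Gy in the reference course): for a 0.60
Gy/fraction gland mean over 20 fractions this gives a factor of 1.25
(12 → 15 Gy) and an NTCP of 5.94%, which is the convention consistent
with the published parotid figures this package reproduces. Full-course
NTCP is computed from the per-fraction mean dose (gEUD at a = 1) times
the number of fractions.

## Synthetic phantom

The generator stands in for CT, contours and beam data; it emulates the
*structure* of a scanned-ion-beam planning problem, not its physics:

- 25 × 25 × 3 voxel grid at 2 mm spacing; voxel centers at
  origin + (index + 0.5) · spacing; flat indices in C order.
- Three geometries: `wrapped_serial` (C-shaped target around a thin
  serial cord — the hard anatomy), `single_gland` (box target with one
  lateral parallel gland), `two_glands_multi_oar` (box target, two
  lateral glands, plus small serial cord and stem in the beam paths).
- Two nearly opposed fields at couch angles −100° and 75°, so both
  beams travel mostly along ±y and the glands sit laterally in ±x. One
  energy layer per 5 mm of target depth span per field; lateral spot
  spacing of one voxel.
- Depth-dose is a parametric surrogate: an entrance plateau (default
  30% of peak) joined to a unit-height Gaussian peak (σ = 3 mm) with a
  sharper distal falloff (σ/2). The optimizer only ever consumes d_ij,
  so any kernel with a plateau, a peak and a distal edge exercises the
  same mathematics; no claim of Bragg-curve realism is made. Lateral
  spread is Gaussian (σ = 4 mm) cut off at 3σ (entries beyond are
  exactly zero, keeping the matrix sparse). The dose constant is 1 Gy
  per particle at the peak voxel, keeping N_j of order one.
- Radiosensitivity: α_ij ramps from α_x far from the Bragg peak to
  rbe_contrast · α_x at the peak (Gaussian ramp of width ~8 mm in the
  recorded peak offset, with a small seeded per-spot width variation);
  √β_ij is constant at √β_x. Defaults α_x = 0.1 Gy⁻¹, β_x = 0.05 Gy⁻²,
  D_t = 30 Gy, s_max = α_x + 2 β_x D_t (the LQ slope at D_t, i.e. a C¹
  continuation — a formula chosen here for smoothness, as only the
  threshold structure matters downstream), rbe_contrast = 3 (a typical
  carbon-ion peak-to-entrance effectiveness ratio).

What the phantom does *not* emulate: CT heterogeneity, nuclear
fragmentation spectra, LET distributions, realistic field numbers or
spot counts (~10² spots here vs ~10⁴–10⁵ clinically), or scanner
deliverability beyond the N_min clamp. Passing tests therefore
demonstrate the correctness of the mathematics (gradients, stepsizes,
descent, metric arithmetic) and the qualitative planning behavior
(gEUD objectives steering the DVH), not dosimetric accuracy on patients.

## Study configurations used by the tests

- DVH shaping (`single_gland`, biological dose, SD, 500 iterations):
  sweeping gEUD₀ = 0.60…0.40 Gy at a = 1, w = 20 drives the achieved
  gland mean dose down monotonically (it tracks gEUD₀ almost exactly)
  while the target mean stays within 1% of the 3 Gy prescription. The
  sweep range sits below the baseline gland mean (~0.64 Gy under a pure
  max-dose plan) so every prescription is active.
- Exponent sweep: (gEUD₀, a) pairs are anchored to the baseline plan as
  gEUD₀(a) = 0.8 · gEUD_a(baseline) — the same fractional tightening at
  every a — for a = 1, 2, 5, 10. The achieved gland maximum dose falls
  from a = 1 through a = 5 and remains below the a = 1 value at a = 10,
  with a small (~1.6%) uptick between a = 5 and a = 10 that persists at
  full convergence on this phantom; the tests assert the endpoint
  decrease and the dominance of a = 1, not four-point monotonicity.
- Plan comparison (`two_glands_multi_oar`, biological dose, CGFR, 1500
  iterations): the voxel-dose plan uses D_max = 2.25 Gy (glands) and
  1.5 Gy (serial OARs) at w = 1; the gEUD plan prescribes
  0.8 × baseline mean at a = 1, w = 20 for the glands and the baseline
  gEUD₂₀ at w = 25 for the serial OARs. This reduces both gland mean
  doses by ~20% (hence their LKB NTCP) at matched target mean (<1%)
  and conformity index (<5%), with serial gEUD₂₀ unchanged within 5%.
- Problem sizes throughout (1875 voxels, ~110 spots, ≤1500 iterations)
  are chosen so the full suite runs in a few minutes on one CPU.

## Numerical choices and degenerate inputs

- Heaviside factors use strict inequalities and are frozen per line
  search; crossings are handled by the halving safeguard.
- gEUD with a < 0 raises on any zero dose (the power mean diverges);
  it is the caller's responsibility to keep target doses positive, and
  the target-gEUD objective reports this as an error rather than
  clipping.
- The closed-form stepsize returns 0 when no term is active or the
  denominator vanishes (already optimal); a non-descent direction is an
  error that callers translate into a CG restart.
- The LKB probit uses the scipy normal CDF (`ndtr`); gEUD uses
  `logsumexp`. Determinism: phantoms, tables and optimization runs are
  bit-reproducible for a fixed (scenario, seed, config).

## Known limitations

- The linearized a > 1 stepsize is a first-order model; the safeguard,
  not the formula, carries the descent guarantee there.
- The biological damping factor f = 0.5 is a fixed heuristic, not
  adaptive; strongly contrasted RBE fields may need many halvings.
- gEUD-based sparing saturates for serial-like organs (high a), where
  the method reproduces, but does not beat, max-dose planning — this is
  expected behavior, not a defect.
- The phantom's two fields and ~10² spots understate the redundancy a
  clinical plan has available for OAR sparing; absolute sparing factors
  on this phantom are illustrative only.
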