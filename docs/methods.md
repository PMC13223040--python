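# Methods

This note documents the models implemented in `bvocmc`, the numerical and
design choices behind them, what the synthetic-data generators emulate, and
the package's known limitations. Every number quoted here is computed by
the test suite or by `scripts/acceptance.py`.

## Transport model

### Governing picture

A single tracer compound is released as an instantaneous point bolus of
mass *m* (mg) at height *H* and carried by a constant mean wind *u* along
+x. Turbulent mixing is parametrized by cumulative spread variables
`r_y(x), r_z(x)` (m²) — the downwind integrals of the eddy diffusivities
divided by *u* — so the lateral and vertical profiles are Gaussian with
variances `2 r_y` and `2 r_z`. A zero-flux ground condition is enforced by
an image source. Stable (Pasquill class F) conditions set the spread
formulas:

```
r_y(x) = 0.08     x² / (1 + 0.0001 x)
r_z(x) = 0.000128 x² / (1 + 0.0003 x)²
```

The vertical formula equals the textbook class-F `σ_z²/2`; the lateral
coefficient 0.08 is 100× the textbook `σ_y²/2` value. Both are provided:
the default `DispersionScheme` uses 0.08, the preset
`pasquill_f_textbook()` uses 0.0008. At metre ranges these formulas give a
very thin plume: σ_z(1 m) ≈ 1.6 cm, a fact that drives several numerical
choices below.

### Field evaluation modes

`as_printed` (default) evaluates the literal closed form with prefactor
`m/(4π r_y r_z)^{3/2}` and streamwise exponent `(x−ut)²/(4 r_y r_z)`,
spreads taken at the field point x. This form is not dimensionally
homogeneous (the streamwise exponent mixes m² and m⁴), but it is the form
against which the package's headline sweeps are defined, so it is kept
verbatim and is the default everywhere.

`consistent` replaces the streamwise spread with `r_x = √(r_y r_z)` and the
prefactor with `m/((4π)^{3/2} √(r_x r_y r_z))`, and evaluates the spreads
at the puff age `u·(t−t0)` rather than at the field point. With
age-parametrized spreads the spatial integral of the field is exactly *m*
(times `exp(−k_eff t)` with decay on), which is what the conservation tests
assert (quadrature tolerance 0.5%); with point-evaluated spreads no such
identity holds. Age parametrization is the classical puff-model convention;
it requires u > 0. In the degenerate limit `r_y = r_z = r` the consistent
mode reduces to the isotropic solution with exponent
`−((x−ut)² + y²)/(4r)` (tested against that closed form directly).

The singular release point (vanishing spread) follows a documented
contract: +∞ exactly on the (drifted) source point, 0 elsewhere, never a
crash. Points with t ≤ t0 return 0.

### Drift and decay

The bolus is treated as a parcel of density ρ_b in air of density
ρ_a = PM/RT; neglecting drag gives the upper-bound centre displacement
`s_z(t) = (ρ_a − ρ_b) g t² / (2 ρ_b)`, negative (sinking) for the default
ρ_b = 1.26 kg/m³. The image term also carries `s_z`, exactly as the
closed form is written. Photochemical loss is pseudo-first-order with
Arrhenius rate `k_eff = A exp(−E_a/RT)`; at the 293.15 K default,
k_eff ≈ 12.3 s⁻¹, so decay — not dilution — dominates the link budget at
metre scales and drives the strong temperature sensitivity of every
downstream quantity.

### Continuous release

`continuous_concentration` superposes puffs released every `quad` seconds
(default 1 ms, matching the simulation step). The railway of narrow puffs
is effectively a spectral (equispaced-trapezoid) quadrature of a smooth
integral, so halving `quad` changes reference-point values well below 1%
(tested).

## Receiver uptake

`Q = ∫₀^τ ∫_V C_l dV dt` over a sphere (default radius 0.15 m, τ = 2 s,
centre (d, 0, z)). Two numerical facts shape the integrator:

1. **The plume sheet is thinner than any affordable 3-D node spacing.**
   σ_z ≈ 1.6 cm at 1 m vs ≈ 2 cm spacing for an 8-node radial rule. The
   default `gauss_erf` rule therefore integrates the vertical Gaussian
   *analytically* over each sphere chord (erf differences) and places
   Gauss–Legendre nodes only in the smooth (x, y) disk (default 12×12).
   It agrees with a dense 24³ spherical Gauss-product rule to 7 significant
   digits and with 4·10⁵-sample Monte Carlo within 1% at the reference
   scene; halving both the node spacing and the time step moves Q by far
   less than 1% (tested). Spherical Gauss-product, midpoint-grid and
   Monte Carlo rules remain available as cross-checks.
2. **The puff transit is milliseconds long.** Time integration is a
   trapezoid on the fixed 1 ms step; because equispaced trapezoid sums of a
   Gaussian are spectrally accurate, 1 ms resolves the ≈1.5 ms-σ transit
   essentially exactly. The integrand is evaluated only inside the transit
   window (streamwise exponent ≥ −60), which changes nothing at double
   precision and makes parameter sweeps cheap.

Receivers near domain boundaries (sphere dipping below ground or upwind of
the source plane) collect nothing from the out-of-domain volume; those
nodes get zero weight rather than raising.

`uptake_sweep` varies one of {d, z, H, u, T, τ} with everything else fixed.
Computed behaviour of the as-printed model worth knowing before use
(all reproduced by the test suite):

* Q(d) is cleanly unimodal (at 285 K, u = 3 m/s, z = 0.6, H = 0.8 the peak
  sits at 1.6 m; at 295 K at 1.2 m). The rise is alignment — the sinking
  puff centre reaches the receiver height only after some travel — and the
  fall is decay plus dilution.
* The per-emitter-height optimal receiver height is z* = H + s_z(d/u): the
  drift drop at the transit time, ≈ 2.7 cm at d = 1 m, u = 3 m/s. The mean
  z*/H over H ∈ [0.5, 1.5] is 0.974. A markedly lower optimum ratio (such
  as ~0.7) arises only if the transit lasts ~1 s (u = 1 m/s).
* Q(T) is strictly decreasing at u ∈ {1, 5, 7} m/s but *not* at u = 3
  (Q(285 K) < Q(295 K) there): at 285 K the slower-sinking plume passes
  farther above the 0.6 m receiver, and the alignment gain at 295 K
  outweighs its faster decay. For the same reason Q(u = 1) > Q(u = 7) at
  285 K at this geometry. These are genuine properties of the implemented
  equations; the acceptance suite asserts the opposite (expected)
  orderings and those cases fail, intentionally and visibly.

## Interfering plant

The neighbour's net effect is a path-scale multiplicative attenuation
`I(α, β) = λ e^{−ξα} exp(−(β−μ)²/σ²)` on Q. `AttenuationModel` fits
(λ, ξ, μ, σ) to observed uptake ratios `Q_I/Q_baseline` by damped least
squares (`scipy.optimize.least_squares`, pure LM when unbounded,
trust-region reflective when the physical bound λ < 1 is requested), with
multi-start from perturbed inits. Fitting ratios removes the unknown
absolute scale. Note the structural degeneracy of single-curve fits: along
one β-curve at fixed α only the product `λ e^{−ξα}` is identifiable, so λ
and ξ from such fits are init-dependent while the fitted curve and R² are
not; fits across several α values identify all four parameters (noiseless
recovery to < 10⁻⁴, tested). The λ < 1 bound is off by default (fits
against α can want λ > 1) and should be switched on for β-curve fits where
pure attenuation is the prior.

## Particle simulator

Construction (the continuous-field counterpart fixes every choice):

* x advances deterministically, `x = u t` (no streamwise diffusion — the
  closed form's streamwise spread is itself an artefact of the r-transform).
* Per step, `y += N(0, 2[r_y(x_new) − r_y(x_old)])` and likewise for z, so
  the cloud's variances are exactly `2 r_y(ut), 2 r_z(ut)` at every step
  (verified against the closed form within 3 SE at 10⁴ particles).
* The drift increment `Δs_z = a(t_new² − t_old²)/2` is deterministic;
  ground reflection is `z ← |z|`.
* Decay lifetimes are pre-drawn exponentials with rate k_eff — equivalent
  in distribution to per-step removal with probability `1 − e^{−k_eff Δt}`
  (survival matches `e^{−k_eff t}` within 3 SE, tested).
* Receiver and interferer are absorbing spheres; the interferer (radius
  α·0.15 m, centred at β·separation on the axis at the receiver's height)
  is checked first within a step. A non-absorbing residence-time tally
  (Σ m_p Δt inside the sphere) estimates the volume-time integral Q
  directly and agrees with the consistent-mode closed form within 5%
  (measured ≈ 0.3% at the baseline).
* Repetitions are disjoint particle blocks of one master-seeded stream;
  decay lifetimes are per-particle and absorbed particles keep consuming
  their walk increments as inert ghosts, so trajectories are *identical*
  across interferer configurations sharing a seed (exact common random
  numbers — a sink can then only ever reduce per-repetition uptake, which
  is asserted as an exact, not statistical, inequality).
* The per-repetition mass ledger (absorbed + intercepted + decayed +
  airborne = released) closes exactly by construction.

Scene defaults for the interference study: emitter, receiver and interferer
at 0.8 m canopy height, 1 m separation, 293.15 K, u = 3 m/s, 10⁴ particles
× 100 repetitions, 0.0016 mg release.

**What the passive-sink construction does and does not reproduce.** A
perfect-sink sphere removes at most its geometric shadow of the plume flux.
Consequently uptake decreases monotonically in α (tested), and at α = 1 the
β-curve shows the expected interior maximum. But at α = 0.1 the interferer
(1.5 cm radius) is far smaller than the plume and the simulated attenuation
is weak and monotone in β — nothing like a λ ≈ 0.5 overall suppression —
and for β ≳ 0.75 the interferer sphere overlaps (at small α, sits wholly
inside) the receiver sphere, a degenerate geometry in which interception
collapses because the receiver absorbs first. The fitted λ-Gaussian
response therefore reaches R² ≈ 0.98 at α = 1.0 but only ≈ 0.87–0.93 at
α ∈ {0.1, 0.5} (minimum reported by the acceptance script ≈ 0.87), and the
acceptance threshold of 0.9912 is not met: reproducing a strong
small-interferer attenuation would require a mechanism beyond passive
absorption (e.g. flow blocking), which is outside this model's stated
assumptions.

## OOK link

A bit-1 pulse is idealized as a single instantaneous bolus at slot start
(the channel model is a puff model; the 100 ms atomizer on-time is below
the slot scale). Per-slot received quantity is the uptake integral over
that slot with the tails of all earlier releases superposed — computed once
as a single-pulse slot-response vector `g[k]` and convolved with the bit
stream. Threshold detection is boundary-inclusive (`quantity ≥ m_th → 1`).
`m_th` is a user input: the model supplies no natural scale for it, and the
BER experiments show the expected behaviour (zero in the noiseless
separated regime, fraction-of-zeros at m_th = 0, non-decreasing as the
threshold climbs past the signal). At u = 3 m/s and 0.5 s slots the puff
clears the receiver within the first slot, so inter-symbol interference is
structurally non-negative but numerically negligible; slower wind or
shorter slots move tail mass into later slots and `g[k]` captures it.

## Capacity

Counts are conditionally Poisson with mean `ξ(m) = m η · counts_per_unit`.
The transport model fixes η but not the count scale;
`calibrate_counts_per_unit()` pins the reference scene (d = 1 m, u = 3 m/s,
T = 295 K, m = 0.0016 mg) to ξ = 100, the moderate-to-high counting regime.
The silence level is an exact point mass at zero — with a noiseless "off"
symbol, binary capacity is within 10⁻⁶ of 1 bit already at ξ ≈ 30, so
capacity sweeps only leave saturation where the sweep drives ξ low
(distance beyond ~1.5 m, temperature above ~300 K, masses below ~10⁻⁴ mg at
the default calibration). Mutual information is an exact truncated
summation (truncation tail 10⁻¹³, verified against a brute-force double
sum to 10⁻⁹); binary capacity is a bounded scalar maximization of the
concave MI (matches a 10⁻⁴-step prior grid within 10⁻⁶ bits), larger
alphabets use Blahut–Arimoto (agrees with the scalar path on a duplicated
binary alphabet to 10⁻⁶). The Gaussian conditional-entropy closed form
`½ log₂(2πe ξ)` is within 1% of the exact Poisson entropy at ξ = 100 and
degrades below ξ ≈ 30 (it crosses zero at ξ = 1/(2πe) — both facts tested).
The capacity-vs-SNR curve is binary-antipodal-input AWGN capacity by
numerical integration — the one standard binary family that saturates at
exactly 1 bit — verified against an independent Gauss–Hermite evaluation.

## Testbed correction model

The corrected field multiplies the dispersion spreads by B₁, B₂, the
nominal drift acceleration by B₃, replaces the Arrhenius rate with an
effective B₄ and scales the amplitude by B₅·I(α, β). With
B₁ = B₂ = B₃ = B₅ = 1 and B₄ = k_eff it reduces pointwise to the attenuated
base field (tested to machine precision). A `literal` mode instead
substitutes B₁, B₂ for the spreads as constants (with the bare drift term
`B₃t²/2`); it is the variant that yields sensible bench-scale (metre,
u ≈ 0) profiles, since the scale-mode streamwise factor is astronomically
small at x ≈ 1 m when u = 0.

**Identifiability dictated the synthetic fixture.** On a max-normalized
trace sampled at one common time, the decay factor `e^{−B₄t}` and amplitude
B₅ are constants and vanish in the normalization — they cannot be
estimated, period. The generator therefore emulates a transect of stations
each read just after the local puff-core passage (every read at
t = x/u + δ), by two stacked sensors: two read delays (1 and 3 ms) make the
streamwise factor vary across stations and pin B₁B₂, and two heights
(0.28/0.36 m, source at 0.4 m) make the sinking core cross each sensor line
at a different distance, separating the drift scale B₃ from the decay B₄.
The station range [0.35, 0.95] m at u = 1 m/s brackets both crossings. This
geometry was chosen by a conditioning study before freezing: worst-case
recovery error over 20 noise realizations at 2% multiplicative noise and
50 reads is 0.8% (B₁), 0.7% (B₂), 0.1% (B₃), 2.6% (B₄). B₅ is held at 1
and reported non-identifiable. Fit residuals are relative,
`(pred − obs)/(obs + 10⁻³·max)`, the maximum-likelihood weighting under the
generator's multiplicative noise — unweighted residuals leave a sloppy
B₁–B₄ trade-off that relative weighting plus the dual-read design removes.
Multi-start draws log-uniform over scales in [0.1, 10] and decay in
[0, 30] s⁻¹, so a ×10-wrong initial guess still reaches the same optimum
(tested).

What passing these fits shows — and what it does not: the pipeline
demonstrates that *if* concentration profiles follow the corrected model
with multiplicative sensor noise, the calibration recovers the corrections
with honest uncertainties. Real metal-oxide gas sensors add baseline drift,
response lag, surface-memory effects and humidity sensitivity, none of
which the generator emulates; recovery on these fixtures says nothing about
those failure modes.

## Seeds and determinism

Every stochastic component takes an explicit integer seed and builds its
own `numpy.random.Generator`; no global random state is touched. The CLI
threads one master seed into each pipeline and embeds the resolved
configuration in every output table, so a table regenerated with the same
seed is byte-identical.

## Known limitations

* Class F only; no humidity/radiation dependence, multi-species chemistry,
  terrain, canopy aerodynamics, or flow modification by obstacles.
* The as-printed field is dimensionally inconsistent by construction; all
  conservation statements hold in the consistent mode only.
* The consistent mode (age-parametrized spreads) is undefined at u = 0.
* The passive-sink interferer cannot reproduce strong attenuation by small
  interferers (see above); the attenuation-fit quality criterion is
  accordingly not met and is reported as computed.
* The receiver is a passive integrating volume: no stomatal kinetics,
  saturation or re-emission.
* Capacity results are idealized memoryless benchmarks; inter-symbol
  dependence is modelled at the link layer but ignored in the capacity
  computation.
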