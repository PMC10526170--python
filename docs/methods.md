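# Methods

## Model and assumptions

The simulator couples a continuum description of a tumoroid embedded in
collagen with a discrete description of individually invading cells, on a
polar domain whose outer ring of nodes represents the perfused channel of
a tumor-on-a-chip device.  The continuum part evolves proliferative-cell
concentration `Cp`, nutrient `n`, collagenase `M` and collagen `f`:

* cell transport is Fickian random motility −D_i∇Cp by default (the
  literature this model family descends from uses a nonconvex free
  energy for collective motion; since no explicit functional is
  available, the default here is the Fickian limit, which is the form
  that can be falsified against an analytic diffusion oracle — an
  experimental density-dependent double-well mobility is provided behind
  the `nonconvex_flux` flag);
* chemotaxis up the nutrient gradient is included with coefficient
  `chi_chem`, default 0, so the base dynamics are diffusion plus
  haptotaxis, which is the parameterized mechanism;
* proliferation and nutrient consumption are Monod in nutrient,
  η_p = eta_max·n/(n_half+n) and λ_p = lambda_max·n/(n_half+n).  No
  constitutive mechanical law is specified for this system, so stress is
  proxied by P_max·Cp/Cp_packing and proliferation is gated off where
  the proxy reaches the critical stress P_cr (1 kPa; ceiling 5 kPa);
* collagenase is lost to binding at rate ζMf; collagen degrades at rate
  δMf with no transport of its own (fibers do not diffuse);
* the tumoroid is assumed radially symmetric (axisymmetric continuum) —
  consistent with the symmetric channel supply — while discrete cells
  move on the full (r, θ) lattice.

Signs follow the standard continuity convention ∂C/∂t = −∇·J with
J_f = −D_i∇Cp and J_d = +chi_chem·Cp·∇n.

The discrete walkers are the single-cell reading of the same transport
operator: discretizing ∂C/∂t = D_i∇²C − χ_hap∇·(C∇f) with conservative
(finite-volume) central differences and interpreting the update as a
master equation yields per-step probabilities of staying or hopping one
node in ±r or ±θ.  Radial hops carry the polar metric factor
r_{j±1/2}/r_j and angular hops use the local arc length r·Δθ, so the
unbiased walk reproduces isotropic planar diffusion (MSD = 4·D_i·t);
collagen differences across faces tilt the rates up the collagen
gradient.  Negative raw coefficients — possible when haptotaxis
overwhelms the random term on a steep gradient — are clipped to zero and
the distribution renormalized, the standard treatment in hybrid
discrete-continuum migration models.

## Units

All quantities are carried in the units in which they are reported for
this system: cm, s, mg/mL for cells and nutrient, molar for collagen and
collagenase, kPa for stress.  The published cell concentration scale
(10⁴ mg/mL) is carried as printed; only ratios of `Cp` to `Cp_packing`
enter the dynamics, so the absolute scale cancels.  float64 spans the
magnitude range comfortably, which is why no internal nondimensional
form is used.  The channel dose in mg/mL converts to molar through a
configurable collagenase molar mass (default 55 000 g/mol, typical of
MMP1/collagenase type I).

## Parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| D_i | cell random motility | 1e-8 | cm²/s |
| D_n | nutrient diffusivity | 4.2e-6 | cm²/s |
| D_M | collagenase diffusivity | 1e-9 | cm²/s |
| χ_hap | haptotaxis coefficient | 2.6e3 | cm²·s⁻¹·M⁻¹ |
| ζ | collagenase binding rate | 1e-6 | s⁻¹·M⁻¹ |
| δ | collagen degradation rate | 1e-2 | s⁻¹·M⁻¹ |
| n₀ | channel nutrient | 4.5 | mg/mL |
| f₀ | initial collagen | 1e-9 | M |
| C_i | initial cell concentration | 1e4 | mg/mL |
| P_cr / P_max | critical / max stress | 1 / 5 | kPa |
| eta_max | max proliferation rate | 1/24 | h⁻¹ |
| n_half | Monod half-saturation | 1.0 | mg/mL |
| lambda_max | consumption per cell conc. | 2e-10 | s⁻¹ per mg/mL |
| Cp_packing | close-packing concentration | 1e5 | mg/mL |

The first eleven rows are literature/proposed values for the U251 +
bovine-collagen system; the Monod constants and packing scale are this
package's defaults: eta_max = 1/24 h⁻¹ matches a fast glioma doubling
time, n_half = 1 mg/mL sits well below the 4.5 mg/mL supply so growth is
only mildly nutrient-limited at the start, and lambda_max is set so the
tumoroid core depletes a visible fraction (~40%) of its nutrient over
the three simulated days.  Cp_packing = 10·C_i places the initial core
at 0.5 kPa, half the critical stress, so the core proliferates until it
doubles.

Geometry defaults: chamber radius R = 0.25 cm, tumoroid radius 0.03 cm,
96 radial nodes, 64 angular slots, three simulated days with snapshots
four times per day.  These were chosen so that the diffusion-driven ring
front (≈0.17 cm advance by day 3 at the published D_i) meets the
collagenase penetration zone — √(4·D_M·t) ≈ 320 µm plus the erfc tail
inward from the channel — late in the run without either front reaching
the absorbing channel wall.  In tighter chambers the farthest live
walker pins at the wall and dose contrasts vanish.

Time stepping is forward Euler at 0.8× the FTCS stability bound
dt ≤ ℓ²/(4·max D) with ℓ the smallest mesh length (the radial spacing
when axisymmetric; the innermost angular arc on a full 2-D grid); the
configuration validator rejects any dt above 0.9× the bound.  Collagen,
having no spatial operator, is integrated exactly per node
(f ← f·exp(−δMΔt)).  The r = 0 node is closed by the finite-volume
symmetry limit 4(u₁−u₀)/Δr².  All fields are floored at zero after each
step; under the stability bound the schemes are positivity-preserving,
so the floor is inert in practice.

## Coupling and shedding

Walkers re-read the collagen field every continuum step (tightest
coupling; a stride is configurable).  Once per simulated hour, lattice
sites in the two-cell radial band behind the ring front spawn a walker
with probability min(1, shed_gain·(Cp/max Cp)·|∂f/∂r|·R/f_ref) — i.e.
proportional to local cell density and local collagen-gradient
magnitude, so untreated runs (no gradient) shed nothing — capped at 600
live+dead walkers.  Spawned mass is not removed from the continuum:
walkers are markers of invading cells, not transported mass, because
ring and finger patterns are quantified as separate, overlapping
measurements.  `shed_gain = 2e6` sets the onset of visible shedding at
the 0.001 mg/mL dose to late day 2 at the default geometry.  One PCG64
stream per run drives shedding and all moves in a fixed order, so runs
are bit-reproducible given the seed; sweep replicates use
seed + 1000·replicate, and the same seed set is shared across doses so
dose contrasts use common random numbers.

## Invasion metrics

The ring front is the outermost radius where the angular-mean Cp is at
least α = 5% of its peak.  L_ring is the front's advance since t = 0;
L_finger the advance of the farthest *live* walker, defaulting to
L_ring when no walker lies beyond the front so L_overall = max(L_ring,
L_finger) is always defined.  The pattern label is "finger" when
L_finger − L_ring exceeds 10% of the initial front radius, "mixed" when
walkers lie beyond the front but within the margin, else "ring".
Invaded area is decomposed explicitly as the annulus swept by the ring
plus one local grid cell (r·Δr·Δθ) per walker beyond the front.

Two-group comparisons use Welch's unequal-variance t-test, replaced by
an exact permutation test on the mean difference whenever a group has
five or fewer replicates (always the case for the 3-replicate chip
design).  Directional claims ("dose A invades farther than B") are
tested one-sided; equality claims two-sided.  At n = 3 vs 3 the smallest
attainable one-sided exact p is 1/20 = 0.05, so significance at
α = 0.05 is inclusive and requires the observed labeling to be the
unique extreme partition; the smallest two-sided p is 0.1, which is why
small-sample equality checks cannot produce false positives.

## Synthetic chip experiment

The generator emulates the *statistical* structure of the invasion
measurements, not their imaging pipeline.  Mean curves follow
L(dose, day) = floor + A·m(dose)·(1 − exp(−day/τ(dose))) with a plateau
multiplier m saturating in dose (half-saturation 1e-4 mg/mL) and a time
constant τ shrinking from 2.0 days (untreated) toward 0.2 days with a
slower dose half-saturation (2e-3 mg/mL).  This family is the simplest
that encodes all of the qualitative facts at once: no dose separation
at day 0 (a 5 µm instrument floor), a clear 0.01 > 0.001 ordering at
day 1 (kinetic speed-up not yet saturated), and treated ≫ untreated but
0.01 ≈ 0.001 at day 3 (plateaus nearly equal).  Replicate noise is
mean-one lognormal with cv 0.15.  No numeric invasion lengths are
published for this system, so the day-3 untreated mean (300 µm) is a
nominal synthetic scale — the generator's output is labeled synthetic
throughout.  What passing tests show is therefore that the analysis
pipeline reproduces the significance *pattern*, not any absolute length.

## Degradation-rate calibration

`fit_degradation_rate` recovers δ by minimizing the summed squared
relative error between observed per-condition mean invasion lengths and
a simulated response table (hybrid runs over a log-spaced δ grid, linear
interpolation in log δ, dense grid search plus parabolic refinement;
bootstrap over replicates for the interval).  A flat objective across
the grid — e.g. data containing only untreated wells — raises an
explicit non-identifiability error.

A structural limitation, measured and documented rather than hidden: at
the published rates the enzyme degrades only ~5×10⁻⁴ of the collagen
over three days, so δ reaches the invasion length almost entirely
through the number of shed walkers N (linear in δ) and the finger
length's extreme-value dependence on N (≈ σ·√(2 ln N)).  The resulting
sensitivity d ln L / d ln δ ≈ 0.07–0.09 is comparable to the relative
noise on a 3-replicate condition mean (0.15/√3 ≈ 0.087), so δ is only
weakly identifiable from noisy invasion lengths: across 20 trials the
median relative recovery error is ≈ 50–80%, far from the ≤ 25% one
might hope for, while noise-free self-generated data recover δ to well
under 5%.  Tightening this would require either a much more
δ-sensitive observable than an extreme-value invasion length or
substantially lower measurement noise; both are fixed features of the
emulated experiment.

## Scaled-down problem sizes

The default configuration (96 radial nodes, three days) runs in a few
minutes on one CPU.  The test suite and the acceptance script use the
same physics on coarser grids chosen for turnaround: 48 radial nodes for
the nine-run dose sweep and 40 for the 28-run δ response table; the
diffusion benchmark uses 128 nodes as its accuracy target requires.

## Known limitations

* The continuum cell flux default is the Fickian limit; aggregation
  effects of a nonconvex free energy (front steepening, phase
  separation) are only available through the experimental flag and are
  untested against data.
* Haptotaxis as printed points up the collagen gradient; with enzyme
  supplied from the channel, the gradient near the degradation zone
  points inward, so haptotaxis slightly opposes invasion there.  The
  dose effect on fingers is carried by gradient-proportional shedding.
* Walkers do not proliferate, collide, or switch migration modes; they
  are absorbed at the channel wall.
* Two-way ANOVA with interactions (the wet-lab analysis) is out of
  scope; the statistical layer provides two-group comparisons only.
* The rheology of the real hydrogel enters only qualitatively: more
  enzyme ⇒ softer, more degraded matrix ⇒ longer invasion, which is the
  monotonicity embedded in the transport model itself.
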