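# Methods

## Model structure and assumptions

The package implements a steady-state FvCB description of C3 net
assimilation coupled to a single slow state variable, the undamaged
fraction `Aj` of linear electron transport. The separation of timescales is
the central assumption: CO2 pools in the intercellular space and chloroplast
stroma equilibrate within tens of seconds, while photodamage accrues over
tens of minutes, so at every time step the two limitation-specific
chloroplast CO2 concentrations are solved as steady states and only `Aj` is
integrated (explicit Euler). Damage is irreversible — there is no repair
term — so simulations are meaningful for stress exposures of about an hour;
recovery over longer horizons is outside the model. Direct thermal
inactivation above ~42 °C, triose-phosphate-export limitation, cyclic and
pseudocyclic electron flows, and within-leaf spatial heterogeneity are
likewise not represented; temperature acts only through the reversible
activity factors.

Clearing each steady-state CO2 balance of its denominators yields a
quadratic in `Cc` whose coefficients satisfy `a > 0, c ≤ 0`, so it has
exactly one positive root, which provably lies between the compensation
point `Γ*` and the zero-consumption equilibrium `Co + Rd/g_tot`
(`g_tot = gs·gm/(gs+gm)`). The solvers return this root in closed form; the
test suite checks the residuals (< 1e-8), cross-checks against a bracketed
root finder, and verifies agreement with brute-force relaxation of the
balance ODEs to 1e-6 relative over randomized parameter draws. The
closed form is also what makes the activity-grid and temperature sweeps
cheap: whole grids are integrated in lockstep as numpy arrays.

The damage law uses the damaged, temperature-scaled electron flow
(`Wj ∝ Aj·Act_J·J`), which makes photodamage self-limiting: as `Aj` falls,
both the flow into the chain and the uncommitted excess `Wj − W` shrink, so
final damage stays bounded — and a leaf can switch from Rubisco to ETC
limitation mid-protocol as its chain erodes. When the two steady roots tie,
the state is flagged ETC-limited.

## Parameters

| name | meaning | default | units |
|---|---|---|---|
| Jmax | maximal electron transport rate | 55 | µmol·m⁻²·s⁻¹ |
| theta | light-response curvature | 0.25 | – |
| beta_prime | PAR fraction absorbed and routed to PSII | 0.23 | – |
| Vcmax | maximal carboxylation rate | 18.2 | µmol·m⁻²·s⁻¹ |
| Gamma_star | CO2 compensation point | 38.6 | ppm |
| Kc | carboxylation Michaelis constant | 260 | ppm |
| Ko_ratio | O/Ko oxygenation term | 200/179 | – |
| Rd | mitochondrial respiration | 1.0 | µmol·m⁻²·s⁻¹ |
| gs | stomatal conductance to CO2 | 0.17 | mol·m⁻²·s⁻¹ |
| gd, dg_max, hill_n, hill_K | gm light response | 0.018, 0.25, 2, 1000 | mixed |
| kd0, alpha | damage rate constant, balanced-flow ratio | 8e-5 s⁻¹, 0.09 | – |
| Co | ambient CO2 | 360 | ppm |
| ETC temperature response | optimum, widths | 31, 36/15.5 | °C |
| Rubisco temperature response | optimum, widths | 25, 22/22 | °C |

Most defaults are the fitted pea values. Three need justification:

* **Ko_ratio.** Taken at face value in ppm, the oxygenation constants
  (O = 200,000, Ko = 179) would make the Rubisco-limited rate vanish.
  Reading Ko in the conventional mbar units gives the dimensionless ratio
  200/179 and an effective Michaelis denominator of ≈ 550.5 ppm, which
  reproduces the reported Vcmax = 18.2 from the reported low-CO2 operating
  point (Cc = 90 ppm). The ratio is a single config value, so the other
  reading can be forced.
* **beta_prime.** Not measurable from published values. Back-solving the
  ETC steady state at the standard light (Cc = 223 ppm, gm = 0.03,
  gs = 0.17) puts the electron flow there near 29 µmol·m⁻²·s⁻¹, implying
  β′ ≈ 0.21–0.23 for Jmax = 55, θ = 0.25. The package uses 0.23, the value
  in that range that also reproduces the reported limitation structure
  (ETC-limited at 108–239, Rubisco-limited at 425–758 µmol·m⁻²·s⁻¹) and
  the multi-phase temperature dependence of final damage at moderate
  light. The conventional leaf-optics estimate (≈ 0.4–0.45) is
  incompatible with those concentrations; β′ remains config-exposed.
* **Rd.** Measured but not published; 1.0 µmol·m⁻²·s⁻¹ is a typical pea
  value and is config-exposed. Final-damage magnitudes at high light shift
  by a few hundredths of Aj across plausible (β′, Rd) pairs; with the
  defaults, the standard one-hour protocol at 758 µmol·m⁻²·s⁻¹ and
  10–42 °C stress temperatures ends with final Aj ≈ 0.69–0.74.

## Protocols and sweeps

The standard protocol is 20 min favorable, 20 min stress, 20 min favorable,
all at the same actinic light. Favorable phases run at 23 °C, the
cultivation temperature. Stress is expressed either as a temperature (acting
through both activity factors) or as direct activity overrides, in which
case the favorable phases hold both activities at exactly 1. The Euler step
defaults to 0.1 s (a convergence test shows < 1e-3 change in final Aj when
halved); states are recorded every 10 s. A "reduced stomatal conductance"
option scales gs throughout the protocol; because the reported 10% change is
ambiguous, both ×0.9 and ×0.1 are exercised in the tests.

## Estimation pipeline

The staged pipeline mirrors field practice, with three deliberate choices:

* **Rd-corrected inversion.** The chloroplast CO2 used to compose stages is
  `Cc = Ci − (A_hv − Rd)/gm`, the exact inverse of the gm estimator
  `gm = (A_hv − Rd)/(Ci − Cc)`; the simpler `Cc = Ci − A_hv/gm` is exposed
  as `cc_from_ci` but neglects respiration (with gm ≈ 0.03 the discrepancy
  is Rd/gm ≈ 30 ppm, enough to push a low-CO2 point below Γ*).
* **Max-rule Cc with fixed-point iteration.** Per-light chloroplast CO2 is
  the larger of the ETC inversion (from A_hv and the PAM electron flow) and
  the Rubisco inversion (from A_hv and Vcmax) — the same selection rule as
  the forward model. Since the Rubisco inversion needs Vcmax, the
  (gm, Vcmax) pair is iterated to self-consistency; one pass suffices when
  the reference light is ETC-limited, and the iteration converges to
  machine precision on noiseless tables either way.
* **Per-pulse damage rates.** The quenching pulse train is interpreted
  per-interval: `kd_i = (qN_{i+1} − qN_i) / (Δt·(1 − qN_i))`, with
  `1 − qN` identified with the undamaged fraction at the interval start and
  the model rates `Wj, W` evaluated at a fresh quasi-steady state for that
  pulse's light, carrying the accumulated `Aj` and the leaf's own stomatal
  conductance. The (kd0, α) fit is bounded least squares on those rates.

All nonlinear fits use bounded least squares from a deterministic five-point
start grid (tolerances 1e-14), report R² = 1 − SS_res/SS_tot, and flag
degeneracies: α is only jointly identifiable with kd0 when every light
level is ETC-limited (`Wj = W`); a temperature optimum fitted outside the
sampled range and a flat gm series are warned about rather than guessed at.

## Synthetic data

The generator emulates the measurement design: four blue-light intensities
(108/239/425/758 µmol·m⁻²·s⁻¹), CO2 at 100/360/2000 ppm, seven temperatures
(10–42 °C), seven replicate leaves, 70-s damage pulses. Observables carry
multiplicative Gaussian noise (default CV 2% on assimilation, yields and
quenching increments); stomatal conductance varies between leaves
(SD 0.06 around 0.17, suppressed at zero noise) and each leaf's gas
exchange is simulated with its own gs. Two idealizations are deliberate and
make noiseless tables exact fixed points of the pipeline: saturating-CO2
rows encode the infinite-Cc calibration relation `A_hv = J/4` exactly, and
all parameterization rows are generated with activity factors of 1, so the
fitted Jmax and Vcmax are reference-condition values. Temperature-activity
observations are emitted pre-normalized (activity 1 at the optimum), the
form in which such series are fitted.

What passing recovery tests show, therefore, is that the pipeline algebra
is correct and stable under instrument-like noise — not that real leaves
satisfy the calibration ideal, lack drift or leaks, or share the generator's
variance structure. Two identifiability limits are worth knowing: the
curvature θ is weakly determined by a four-light design (its repeated-draw
spread at 2% noise is an order of magnitude wider than that of Jmax), and
the gm saturation parameters (Δg_max, K) are poorly constrained when the
brightest light sits below the half-saturation intensity, even though the
fitted curve itself is accurate over the sampled range.

## Known limitations

* No damage recovery, no direct thermal damage: predictions above ~42 °C or
  beyond ~1 h horizons are extrapolations the model is not built for.
* Under strict ETC limitation the damage rate is `α·kd0·Wj`, so anything
  that lowers chloroplast CO2 (e.g. stomatal closure at low light) slightly
  *reduces* modelled damage there; the damage-promoting effect of stomatal
  closure appears at the Rubisco-limited (higher-light) conditions.
* Stomata are static (a scale on gs); no stomatal dynamics.
* Explicit Euler only — adequate because the damage ODE is slow and smooth;
  no stiff integrator is provided.
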