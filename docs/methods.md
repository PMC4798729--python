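# Methods

`lineagemorph` simulates unbranched stem-cell lineages whose self-renewal
is under mixed diffusible feedback, at three levels of description: a
well-mixed ODE model, a piecewise-deterministic stochastic ensemble, and
a 2D multiphase continuum model of a growing epithelium. This note
records the models, the numerical choices, and the judgment calls made
where the design was genuinely open.

## Well-mixed lineage models

**Two-stage lineage.** Stem/progenitor cells χ0 self-renew with
probability P and differentiate into terminal cells χ1 that turn over at
relative rate δ = d/v (time τ in cell cycles):

    dχ0/dτ = (2P − 1) χ0
    dχ1/dτ = 2 (1 − P) χ0 − δ χ1

Feedback enters through P. The default *product-of-Hill-functions* form

    P = p · (φ χ_pos / (1 + φ χ_pos)) · 1 / (1 + γ χ_neg)

is saturating and non-negative by construction: φ is the gain of a
renewal-promoting factor (FGF-like), γ of a differentiation-promoting
factor (GDF11-like), p ∈ (0, 1] the maximal renewal probability. The
alternative *shared-denominator* form `P = p φ χ_pos / (1 + φ χ_pos +
γ χ_neg)` is also implemented; it removes bistability (see the behavior
census below). Both feedback sources default to the TD population in the
two-stage model; the three-stage model (constant SC influx ζχ0 into a
committed-progenitor compartment) wires positive feedback from the CPs
and negative from the TDs.

**Equilibria and bistability.** Setting P = 1/2 gives the equilibrium
quadratic γφχ² + (γ + φ − 2pφ)χ + 1 = 0. Besides the always-stable
extinct state, two positive roots (low = unstable saddle-node partner,
high = stable) exist iff p > 1/2 and r = φ/γ exceeds

    r* = (2p + 1 + 2 √(2p)) / (2p − 1)²,

the larger root of (2p−1)²r² − (4p+2)r + 1 = 0. At p = 1, r* = 3 + 2√2 ≈
5.83. At every non-zero equilibrium P = 1/2 exactly and χ0 = δχ1. The
same two roots bound the *growth-leap* window of the δ = 0 (final-state)
system: between them the SC pool transiently expands; trajectories are
classified as regime 1 (start above the window), regime 3 (carried
through and past it) or regime 2 (SC exhausted below it).

A caution discovered while validating the dynamic threshold: r* is the
*existence* threshold. The basin boundary from a particular initial
condition lies above it — from (χ0, χ1) = (0.3, 0), bisection puts the
extinction/growth switch at φ/γ ≈ 6.9, approaching 5.83 only for larger
initial SC pools. Both numbers are reported by the test suite; the
analytic threshold is the sharp quantity.

**Exogenous pulses** add inside the Hill arguments: positive term
φχ + φ_ex, negative denominator 1 + γχ + γ_ex. The composition rule is a
modeling choice (the alternative — multiplying saturated Hill terms —
cannot raise P once the endogenous term saturates, and could not toggle
the system as observed); with it, a two-cycle φ_ex = 200 pulse drives the
bistable system to its high state and a later γ_ex = 200 pulse back to
extinction.

**Behavior census.** Long-run fates (zero / non-zero / unbounded) are
measured by integrating from a scale-aware grid of initial conditions
with divergence detection. Bistability (steady state) requires a stable
extinct state coexisting with a downward P = 1/2 crossing; bimodality
(final state) is ultrasensitive initial-condition switching with an
extinction-capable slow mode, detected from the sign pattern of P − 1/2
over χ: it must start negative and contain a positive region. This
reproduces the full product-form outcome table; for the
shared-denominator variant it reproduces the steady-state entries, while
the final-state bimodality cell is intrinsically ambiguous (no single
definition separates it from the positive-feedback-only row) and is
documented rather than asserted.

## Stochastic ensembles

The dominant noise source is randomness in division outcomes, modeled as
a truncated-normal redraw of the maximal renewal probability p once per
cell cycle (held constant in between), with optionally noisy initial
conditions; variance defaults to 0.1 and the endpoint is read at cycle
200. All realizations advance together through a vectorized fixed-step
RK4 integrator (dt = 0.01 cycles), so the zero-variance ensemble is
bit-identical to the deterministic `rk4` path. Endpoints are summarized
by histograms (Freedman–Diaconis bins, guarded against outlier-dominated
bin counts), mode locations, and the fraction of realizations below the
deterministic unstable root (the extinction classifier). Because
extinction is absorbing under per-cycle noise, the φ/γ needed for
*reliable* non-extinction is far above the deterministic threshold: with
variance 0.1 the zero-mode / bimodal / non-zero-mode regimes sit near
φ/γ ≈ 7 / 60 / 200 (the ensemble presets encode these).

## Spatial continuum model

Volume fractions on a uniform cell-centered grid over
[−20, 20] × [−10, 10] (default): CP χ1, TD χ2, stroma χS, fluid χL, with
χ1 + χ2 + χS + χL = 1 pointwise. The stem-cell population is a *surface
band* pinned to the basement membrane — the sharp-interface limit
A(t)·δ_BM — carried as the field χ0 = A·(χ_bulk·χS) with A renormalized
every step so ∫χ0 stays constant however the BM deforms; it contributes
the source v0χ0 of new CPs and is excluded from the bulk partition of
unity (it occupies no volume).

Per step, in the quasi-steady order (factor diffusion is minutes, growth
is hours):

1. **Factors.** Each factor C ∈ {F, G} solves
   0 = ∇·(D(1−χL)∇C) + s1χ1 + s2χ2 − (d0 + u1χ1 + u_S χS) C + ExtSrc.
   The (1−χL) diffusivity implements the apical no-flux condition in the
   diffuse-domain sense; the basal side diffuses freely into the stroma,
   where G may be absorbed at rate u_S (follistatin-like sink).
   Exogenous sources are stromal relaxation terms α(A − C)χS toward a
   Gaussian target A anchored to the leftmost BM height. The discrete
   system is an M-matrix (solutions non-negative) solved by sparse LU.
2. **Renewal field.** p1 = p1_min + (p1_max − p1_min)·(φF/(1+φF))/(1+γG).
3. **Sources.** Srcχ1 = v0χ0 + v1(2p1−1)χ1, Srcχ2 = 2v1(1−p1)χ1 − dχ2.
4. **Mechanics.** Darcy flow u = −κ(∇p − (λ/ε) μ ∇χT) with the
   Cahn–Hilliard chemical potential μ = f′(χT) − ε²∇²χT,
   f = ¼χ²(1−χ)², and pressure from −∇·(κ∇p) = SrcχT − ∇·(κ(λ/ε)μ∇χT),
   homogeneous Dirichlet p (tissue can leave the box smoothly). The λ/ε
   scaling is used identically in the velocity and the pressure equation;
   this is the thermodynamically consistent pairing for the adhesion
   energy E = (1/ε)∫λ(f + (ε²/2)|∇χT|²), and the discrete E (face-based
   gradient energy, the exact Lyapunov functional of the matched
   stencils) is verified non-increasing without sources.
5. **Transport.** ∂χi/∂t = −∇·(−Mχi∇μ) − ∇·(uχi) + Srcχi with upwind
   advection; stroma and fluid absorb the counter-flux −J_T in
   proportion to their local fractions. Advection and reactions are
   explicit; a constant-coefficient biharmonic stabilization is applied
   implicitly (one cached sparse factorization), lifting the fourth-order
   step restriction. All face/cell stencils are built from the same 1D
   difference matrices, so the discrete divergence of u equals SrcχT to
   machine precision every step.

Steps that push fractions outside [0, 1] by more than 0.1 are rejected
and retried at halved dt (small interface under/overshoots are inherent
to diffuse-interface transport and are clipped; treating violations
above ~1e−10 as hard errors would make any practical step size
unusable). Default dt = 0.005–0.01 cycles; runs terminate at t_end,
extinction (epithelial area < 1% of initial), or when the tissue reaches
the domain boundary.

**Growth geometry.** With the stromal G sink, growth concentrates at the
basement membrane and the epithelium invades *downward into the stroma* —
the crypt-like downgrowth geometry. Budding and fingering scenarios
measure BM excursions in that direction.

## Parameter calibration of the spatial scenarios

Caption-stated values are taken as given: φ = 3.0/4.0 (bimodal-growth
pair), φ/γ = 0.6–0.7 with γ = 5.0 (fingering), D_F = D_G (equal
diffusivities — the anti-Turing point), TD-derived production 0.5, the
S24 noise recipe with baseline 2.0. The remaining dimensionless rates
are not available in the provided material and were calibrated once to
reproduce the qualitative figure behaviors, then frozen in the scenario
presets:

* Bimodal growth (`fig3g_*` presets): d = 0.5, F: D = 1, s1 = 0.5,
  d0 = 0.2; G: D = 1, s2 = 0.5, d0 = 2.0, stromal uptake 2.0;
  p1 ∈ [0.1, 1.0]; κ = 1, λ = 0.1, ε = 0.4, M = 0.02, SC mass 4.
  With these, φ = 3.0 peaks near cycle 4 and declines thereafter while
  φ = 4.0 sustains near-exponential growth — the intended ultrasensitive
  outcome pair.
* Budding (`fig4`/`fig5*` presets): same, with a stromal Gaussian F source at
  the lower-left BM (magnitude 5, relaxation rate 2). A sharply
  demarcated bud grows at the source while the distal epithelium
  declines. Removing the source after cycle 12 leaves a self-sustaining
  bud (φ = 3.3); a strong stromal G pulse (magnitude 50, cycles 15–19)
  knocks the bud down to less than half its size and growth stays far
  below the untreated trajectory — a slow regrowth follows at late times
  because the conserved stem-cell band keeps seeding progenitors at the
  BM, so a *permanently* arrested state is not reachable in this
  formulation.
* Fingering (`fig7_*` presets): reduced factor spread (D = 0.1 for both
  factors; in-tissue decay lengths 0.58 for F and 0.35 for G — equalizing
  them destabilized the flat epithelium faster than fingers could form at
  coarse resolution) with strong stromal G uptake (rate 5) and faster TD
  turnover (d = 1). An exogenous stromal F source triggers a localized
  invading downgrowth; after the source is removed at cycle 15 the
  structure self-sustains and its width stabilizes near 18–21 decay
  lengths (reported in units of the larger of the two in-tissue decay
  lengths, the conservative choice).
* Self-organization (`fig8_*` presets): the broad-parameter family with
  φ/γ = 0.66–0.7 and the five-term sinusoidal BM noise recipe. At the
  coarse tier the contour's spectral power is pruned at high frequencies
  but the dominant component remains the strongest seeded harmonic; the
  spontaneous redistribution into the 2–4 cycles-per-width band seen at
  larger scale separations requires finer grids (a 256 × 128, ε = 0.25
  probe does develop the interface instability) and is documented as a
  resolution limitation rather than asserted at desk scale.

The coarse tier runs at 128 × 64 (h = 0.3125, ε = 0.4 ≈ 1.3h) with
dt = 0.01; the fine tier doubles the grid. Problem sizes were chosen so
every preset completes on a laptop-class single core in minutes; the
outcome-class assertions are made at the coarse tier and spot-checked at
higher resolution.

## Morphometrics

The BM is traced as the 0.5 level set of χS (scikit-image contour
tracing, longest contour), resampled uniformly in relative arc length —
so overhanging fingers remain measurable, with the outermost crossing
convention. Periodograms use the mean-removed FFT of the height profile
with one-sided normalization (linear powers over f > 0 sum exactly to
the profile variance); power is reported in dB floored at −160.
Frequencies are in cycles per domain width. The spectral moment is the
power-weighted centroid over f > 0; fingers are connected height
excursions above 20% of the maximum (periodic wraparound respected),
with length = peak excursion and width = arc-length extent at half the
finger's length — the half-length convention is this package's
definition, as the original measurement protocol is unstated.

## What the synthetic scenarios do and do not show

The generators produce idealized strips with tanh interfaces and
noise-free (or recipe-perturbed) geometry; passing tests demonstrate the
internal consistency of the models and the qualitative phenomena
(bistability, ultrasensitive toggling, localized budding, downgrowth,
spectral redistribution), not quantitative agreement with any real
tissue. Real epithelia have cellular granularity, anisotropic mechanics,
and heterogeneous stroma that the mixture model deliberately omits. The
continuum scenarios are also resolution-limited: structures narrower
than ~2 grid cells or than the interface width ε are not trustworthy,
which is why the coarse-tier assertions are about outcome classes and
integrated quantities rather than pointwise fields.

## Known limitations

* The uniform-grid solver replaces the adaptive multigrid approach of
  the literature it follows; very thin fingers at large domain sizes are
  out of reach at the default resolutions.
* The SC band model conserves total SC mass globally; it does not model
  SC redistribution dynamics along the BM.
* Pressure uses a constant motility κ; viscoelastic or multi-velocity
  constitutive laws are not implemented.
* The stochastic module models parameter noise on ODEs, not discrete
  birth–death processes; it is inappropriate at very small populations
  where integer effects dominate.
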