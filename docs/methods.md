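# Methods

This note documents the physics models, parameter choices and numerical
methods behind `fragmon`, what the fragment generator does and does not
emulate, and the known limitations.

## 1. Ion transport (`fragmon.transport`)

**Stopping power.** Uncorrected relativistic Bethe–Bloch:

S(E) = K z² (Z/A) ρ / β² · [½ ln(2 mₑ c² β²γ² T_max / I²) − β²]

with K = 0.307075 MeV·cm²/mol, the full two-body kinematic maximum energy
transfer T_max (no low-β approximation), and no density-effect or shell
corrections. Mean excitation energies: water I = 75 eV, PMMA I = 74 eV.
Compositions by mass fraction (water H₂O, PMMA C₅H₈O₂); densities
1.0 and 1.19 g/cm³ (overridable per region).

*Validity window:* 0.5–500 MeV/u. Outside it the uncorrected formula is
unreliable (shell corrections below, density effect above) and the library
raises instead of extrapolating.

**CSDA range.** R(E) = ∫ dE′/S(E′) from a fixed cutoff of 1 MeV/u, by
adaptive quadrature (relative tolerance 1e-8). The residual range below
1 MeV/u is ~micrometres and irrelevant at the millimetre scales of
interest. Slab transport and its inverse ("what was the energy before this
thickness?") are solved by bracketed root-finding (Brent, tolerance
1e-9 MeV) on the range–energy relation, which makes forward/inverse an
exact round trip by construction.

The uncorrected model reproduces reference proton stopping powers and
ranges in water at the sub-percent level in the therapeutic window, and
puts the 220 MeV/u carbon Bragg depth in PMMA at 8.83 cm, within 1% of the
Monte-Carlo-derived 8.90 cm used as the reference.

**Per-fragment fast path.** Fragment-by-fragment transport uses a
precomputed range table (4000-point log grid, monotone PCHIP interpolation
both ways) rather than per-track quadrature; interpolation error is far
below the detector resolution.

## 2. Phantom geometry (`fragmon.geometry`)

Phantoms are ordered lists of regions (sphere / box / cylinder + material
+ optional density override); where regions overlap, the **last listed
wins**, so inserts are listed after their host. Chord lengths through a
region are computed analytically by slicing the ray at all solid
boundaries and attributing each segment to its owner at the segment
midpoint. Water-equivalent thickness is Σ L·(ρ/ρ_w)·f_mat with a
stopping-power ratio factor f (1.0 for water, 1.16/1.19 for PMMA, i.e. the
stopping-power ratio at the reference density). The WET of a path is what
both the absorption model and the LUT axis consume, so heterogeneous
targets reduce to a single thickness variable.

`exit_path_thickness(vertex, direction, phantom)` is the WET from an
interior emission point to the surface — the "x" of the absorption
weighting. It raises if the vertex lies outside the phantom.

## 3. Emission generator (`fragmon.emission`)

The generator is phenomenological: it emulates the *measured properties* of
secondary-fragment emission, not the underlying nuclear physics.

**Longitudinal density.** A double-logistic in the beam-axis coordinate u:
rising edge centred at the phantom entrance (width 0.4 cm), falling edge at
0.65 of the primary range Δ_beam past the entrance (width 1.7 cm), flat
background at 5% of the plateau, and a hard truncation at the primary range
(no fragments are produced beyond where the beam stops). With these
defaults the fitted 40% width of the generated profile is ≈ 0.74 Δ_beam,
matching the reference measurement (6.6 cm at a 8.9 cm range). The hard
truncation leaves a small cliff (~14% of plateau) at the range that a pure
double-logistic cannot follow; at the track statistics of interest
(10³–10⁴) this is invisible, but on very-high-statistics histograms it
inflates the fit χ² and pulls the fitted fall width below the generator's
1.7 cm. The observables are extracted from the *fitted* curve in all cases,
consistently for data and LUT, so the bias cancels where it matters.

**Spectrum.** Exponential in kinetic energy with decay constant 83 MeV
above a 7 MeV production threshold, truncated at 250 MeV — a one-parameter
stand-in for the measured emission spectra of fast secondary protons.

**Yields.** Detected-fragment yields per primary per steradian:
12.59×10⁻³ sr⁻¹ at 60° and 2.74×10⁻³ sr⁻¹ at 90° (linear interpolation in
between, error outside — no extrapolated angles). Rate arithmetic is
count = N_primaries × yield(θ) × ΔΩ.

**Survival.** A fragment emitted with energy E at exit-path WET x escapes
with probability p = 1{E ≥ E_min(x)} · exp(−x/λ) where E_min(x) is the
proton energy whose water range equals x (range cut) and λ = 80 cm WET is
an effective nuclear-interaction length. Survival can enter either as a
per-track statistical weight (variance-reduced, the default) or as a
sampled Bernoulli decision (true counting statistics, used for dispersion
studies).

**Multiple scattering.** The exit direction is smeared with the Highland
formula θ₀ = 13.6 MeV/(βcp) · z · √t · (1 + 0.038 ln t), t the exit WET in
water radiation lengths (X₀ = 36.08 g/cm²), evaluated at the mean of
emission and exit energy. The smearing rotates the direction *at the
vertex*; in reality scattering displaces the apparent line of flight as
well, so the simulated POCA blur from scattering is slightly optimistic.

**Importance sampling.** Directions are drawn uniformly in a cone around
the detector direction (default half-angle 0.35 rad; the canonical setups
use 0.12 rad) rather than isotropically; yields, not the sampling cone,
carry the absolute normalisation. In the canonical setups the cone is
narrow enough that every sampled direction hits the active area, making
the geometric acceptance uniform along the profile — the tracker is aimed
at the centre of the emission region (its `reference` point), as a real
monitoring device is aimed at the irradiated volume. A misaimed tracker
introduces a z-dependent acceptance that the absorption weight cannot
correct (the weight cancels acceptance by construction), which is a real
experimental constraint, not just a simulation detail.

**What is not emulated:** nuclear reaction kinematics and species mix
(everything is a proton), the angular dependence of the emission spectrum,
target fragmentation, prompt photon and neutron backgrounds, in-phantom
secondary interactions of fragments, and dose delivery structure.

## 4. Detection and reconstruction (`fragmon.detection`)

A planar tracker (angle θ from the beam, distance d from the aim point,
active area a×b, default 20×20 cm at 40 cm) accepts tracks whose straight
line crosses the active area, thins by efficiency, and smears crossing
point (Gaussian in-plane, σ_point = 0.02 cm in the canonical setups) and
direction (Gaussian in two orthogonal planes, σ_ang = 4 mrad). The solid
angle uses the exact pyramid formula for an on-axis rectangle
(0.2354 sr for 20×20 at 40 cm).

The emission-point estimate is the point on the *beam line* closest to the
measured track line (closed-form line–line POCA; parallel lines raise).
The distance of closest approach is kept per track as a quality metric.
The longitudinal profile is a weighted histogram of the POCA points
projected on the beam axis (0.2 cm bins by default), with per-bin errors
√Σw².

## 5. Profile analysis (`fragmon.profiles`)

Two fall-off models: `a + b·erfc[c(x−d)]` for the distal edge alone and
the double-logistic f(x) = p0/(1+e^{(x−p1)/p2})/(1+e^{−(x−p3)/p4}) + p5
for the full profile, optionally convolved numerically with a Gaussian of
width σ_beam·|cot θ| (the beam-spot shadow at non-orthogonal viewing,
exactly zero at 90°). Fits are weighted least squares with per-bin
variance max(count, 1), bounded parameters, quantile-based initialisation
and up to 5 jittered restarts; degenerate outcomes (edge ordering p1 ≤ p3,
non-positive widths) are rejected.

Observables of the fitted curve: the 40% level is taken above the fitted
background, level = p5 + 0.4(f_max − p5), making Δ40 invariant under
background shifts. X_left/X_right are the outermost bracketed roots of
f = level; Δ40 = X_right − X_left; δ40 extends X_right to the intercept of
the tangent at X_right with the background level. In the well-separated
limit these reduce to X_right = p1 + p2·ln 1.5, X_left = p3 − p4·ln 1.5,
δ40 = Δ40 + (5/3)p2, which the implementation matches to 1e-6 cm.
Uncertainties are propagated from the fit covariance with a numerical
Jacobian. Dispersions at fixed statistics come from disjoint (default) or
bootstrap resampling; a single sample reports its dispersion as missing,
never zero.

## 6. Absorption unfolding (`fragmon.unfolding`)

In heterogeneous targets the exit-path WET x varies with emission depth z,
so absorption distorts the detected profile shape. The correction
generalises the profile to f(z, x): for each node of a thickness grid
(default 2.5–10 cm in 1.5 cm steps) the full chain is simulated with the
exit path *forced* to that thickness, the resulting per-primary profile is
fitted, and each double-logistic parameter is modelled as a degree-2
polynomial in x. Each detected track then gets the weight

w(z, x) = f(z, x₀) / f(z, x),  x₀ = 2.5 cm,

with its reconstructed z (POCA projection) and re-traced x (exit WET from
the reconstructed vertex along the measured direction — the role a CT
would play in practice). This direction of the ratio *restores* counts
lost at large x. Weights are capped at 20 and the denominator floored at
10⁻³ of the reference maximum, so a mismodelled tail can never inject
unbounded spikes; capped fractions above 1% are reported as warnings.
Thicknesses outside the LUT span raise by default (`clip` and
`extrapolate` are opt-in). The sphere demonstration uses a wider grid
(2.5–13 cm) because its exit paths reach ~12 cm WET, plus `clip` for the
thin sliver below 2.5 cm near the surface.

Validation compares corrected and uncorrected track samples against the
generated emission sample with a weighted two-sample Kolmogorov–Smirnov
test (effective sample size (Σw)²/Σw²): at 2×10⁴ tracks the uncorrected
profile is rejected (p ~ 10⁻⁵⁷) and the corrected one is compatible
(p ≈ 0.1).

## 7. Reproducibility and numerics

All randomness flows from one master seed through `numpy.SeedSequence`
with one spawned substream per stage (emission, survival, scattering,
detection, LUT), so changing a downstream setting never perturbs an
upstream sample, and identical config + seed give identical outputs. CSV
artifacts are stamped with a 16-hex-digit hash of the config. Problem
sizes in the tests and examples (10³–10⁵ tracks) are chosen for desk-scale
runtimes; they are the package's own study conditions, not claims about
any experiment's statistics.

## 8. Limitations

- Single fragment species (protons) with one global spectrum; no
  angle–energy correlation.
- Uncorrected Bethe–Bloch (no shell/density corrections, no straggling);
  ranges are CSDA means, not distributions.
- Scattering rotates at the vertex (no lateral displacement term).
- The double-logistic is both the generator and the fit model except for
  the truncation cliff at the primary range (see section 3); agreement between
  generator and fit is therefore structural, and the package validates the
  *chain* (reconstruction, dispersion scaling, unfolding), not the nuclear
  physics.
- The LUT assumes the profile *shape* at fixed x factorises from the
  acceptance; a tracker not aimed at the emission region violates this.
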