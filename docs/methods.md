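# Methods

## The two-state adsorption model

The model compares exactly two lipid states: a bilayer dispersed in bulk
solution and a monolayer adsorbed tails-down on the substrate.  Writing
the transfer as (i) separating the two bilayer leaflets across vacuum
(cost `w_ll/2` per monolayer area), (ii) de-wetting the substrate patch
(cost `γ·cos θ`, by Young's equation equal to the substrate–vapor minus
substrate–solvent tension), and (iii) attaching the monolayer to the dry
substrate (gain `w_sl`), gives

    ΔF/A = w_ll/2 − w_sl(θ) + γ·cos θ.

Assumptions inherited from this construction:

- Adhesion is dominated by dispersion interactions of the alkyl tails;
  the head groups are spectators.  This restricts validity to noncharged,
  weakly polarizable substrates.
- Bilayer adsorption energies (≲ 1 mN/m) are negligible against the tens
  of mN/m here, so "bilayer" means "bilayer anywhere in the system".
- The area per lipid is the same in the monolayer and the bilayer; since
  all energies are per area, modest area changes drop out.
- Kinetics are out of scope: the model says which state is stable, not
  how fast it is reached.

The substrate–lipid adhesion law `w_sl(θ)` is linear through the two
measured anchors (0°, 57 mN/m) and (113°, 52 mN/m).  Only these endpoint
values are available at full precision, so the default model is the exact
two-point line rather than a multi-point regression; with it the in-water
threshold solves to θ_ads = 65.73° (reported as 66°) and the equivalent
angle of the air–water interface to θ* = 105.9°.  A multi-point fit of
the underlying adhesion measurements would shift θ* by about a degree
(toward 107°) while leaving θ_ads at 66°; the package accepts arbitrary
anchors via `AdhesionModel.from_wsl_points` for users who have their own
adhesion data.

## Parameters that matter

| parameter | meaning | default | unit |
|---|---|---|---|
| `wll` | leaflet–leaflet work of adhesion | 49 | mN/m |
| `wsl_intercept`, `wsl_slope` | linear substrate–lipid adhesion law | 57, −5/113 | mN/m, mN/m/° |
| `gamma` | solvent surface tension | 72 (water) | mN/m |
| `gamma_alc` | organic-endpoint surface tension | 22 (ethanol) | mN/m |
| `solubility_limit` | mole fraction where micellization breaks the two-state picture | 0.20 | — |
| `iso_fraction` | droplet interface iso-level | 0.5 of bulk density | — |
| `z_excl` | near-substrate exclusion height in the circle fit | 0.8 | nm |

Angle convention: degrees at every interface, radians only inside
trigonometric evaluation.  Headline values are reported rounded
half-away-from-zero to integer degrees / mN/m, and the rounding is stated
wherever such a value is written.

## Solvent exchange

For a binary water/organic mixture the works of adhesion are held exactly
solvent-independent (alcohol swells the layers laterally but barely
changes the per-area adhesion), so composition enters only through the
adhesion tension.  Following the revised Zisman relation (cos θ linear in
1/γ on a fixed solid), the adhesion tension is a straight line in γ fixed
by two boundary conditions — neat water (γ_w, θ_w) and the neat organic,
which wets nearly completely (γ·cos θ → γ_alc):

    γ·cos θ = γ_alc + (γ − γ_alc)·(γ_w·cos θ_w − γ_alc)/(γ_w − γ_alc).

The slope changes sign at cos θ_wc = γ_alc/γ_w (72.2° for ethanol/water).
In the free-energy profiles the weakly varying w_sl is evaluated at one
common angle (default: the in-water θ_ads, overridable per substrate), so
all substrates share the exact neat-organic limit w_ll/2 − w_sl + γ_alc =
−7.6 mN/m (reported as −8); evaluating w_sl at each substrate's own θ_w
instead would spread this limit by the ~10% spread of w_sl.  Profiles
beyond 20 mol% are computed but flagged `beyond_solubility_limit`.

γ(x) is whatever the user supplies: the default fit is a monotone
shape-preserving piecewise-cubic (PCHIP) interpolant that reproduces any
table without inventing chemistry; a three-parameter exponential-decay
form is available for noisy data, and non-monotone tables are isotonically
pre-smoothed with a warning.  A per-point exclusion mask handles
off-trend measurements.

## Droplet contact angles

Cylindrical (quasi-2-D) droplets have circular-cap cross-sections and no
line-tension contribution.  The pipeline: (1) locate the liquid–vapor
interface as the marching-squares contour of the time-averaged density at
half the bulk density (the conventional Gibbs-dividing choice), with
sub-bin linear interpolation; (2) fit a circle by algebraic (Kåsa) least
squares polished by a geometric Gauss–Newton refinement, excluding points
within 0.8 nm of the substrate plane where density layering bends the
contour; (3) compute cos θ = (z0 − zc)/R at the substrate plane;
(4) extrapolate cos θ of droplets of several sizes linearly in 1/R to the
macroscopic limit.  1/R on cos θ is a documented default that absorbs the
residual finite-size bias of small droplets; other extrapolation
variables are possible and would need the user's own convergence study.

On noiseless synthetic caps with interface width 0.4 nm the pipeline
recovers true angles within 2° across 30°–150°, is insensitive to the
exclusion height within 1° over 0.5–1.2 nm, and moves < 0.5° under a
halving of the grid spacing.

## Work of adhesion

Pressure–distance curves P(D) (bar vs nm, attraction negative) are
integrated as w = −∫ P dD from the contact separation to the last sample
by the trapezoid rule, converted with the exact factor 1 bar·nm =
0.1 mN/m; the sign convention makes adhesive curves give positive w.  The
default contact bound is the pressure zero-crossing nearest the minimum
of the running integral (the equilibrium separation between repulsive
core and attractive well), overridable.  The unsampled dispersion tail
can be extended analytically by fitting P ≈ −C/Dⁿ to the outermost
quartile of points; exponents n ≤ 1 are rejected as non-integrable.
On smooth synthetic curves the error is second order in the grid spacing
(~4× reduction per doubling) and below 1% at 200 points.

## Synthetic data

The generators emulate the study conditions, not raw simulation output:

- **Droplet fields**: ideal circular caps, density
  ρ_bulk·½(1 − tanh(2(d − R)/w)) with d the distance from the cap center
  placed so the substrate plane cuts the circle at the prescribed angle;
  w = 0.4 nm default interface width (10–90 distance ≈ 1.1 w, a realistic
  ambient water–vapor width), bulk density 33.4 nm⁻³ (liquid water number
  density), grid spacing 0.1 nm, optional additive Gaussian noise.  They
  contain no near-wall layering oscillations, capillary-wave broadening
  or correlated sampling noise, so passing recovery tests bounds
  discretization and fitting errors only, not the statistical quality of
  real density maps.
- **Droplet series** impose cos θ(R) = cos θ∞ + k/R to exercise the
  finite-size extrapolation (k = 0.3 nm default, the scale of sub-degree
  biases at R ≈ 10 nm).
- **Pressure–distance curves**: 9-3 (repulsive core, D⁻³ dispersion tail,
  zero crossing at σ) or pure power law, each with its closed-form
  integral attached as the oracle; the adhesion driver scales the 9-3
  amplitude so the exact work is the 49 mN/m leaflet-separation value.
- **Mixture tables**: γ(x) decaying 72 → 22 mN/m, default exponential
  with decay scale 0.17 mole fraction, chosen to match the steep initial
  tension drop of ethanol/water (γ(0.2) ≈ 37 mN/m); adhesion-tension
  columns generated exactly from the two-endpoint line.  Because the
  synthetic γ(x) is not the experimentally fitted curve, composition
  landmarks that depend on the real data — e.g. the mole fraction where a
  θ_w = 45° substrate turns adsorbing, or the θ_ads value reached at
  20 mol% — are reproduced qualitatively, not numerically.

All generators are seeded and bit-reproducible, and every generator
returns a truth record with its generating parameters.

## Numerical choices

- Angle equations are solved by sign-change scanning on a 0.1° grid
  followed by bisection to a residual below 1e−9 mN/m — deterministic and
  derivative-free; with the default model ΔF(θ) is strictly decreasing on
  [5°, 175°] (γ·sin θ dominates the w_sl slope), so the root is unique.
  If several sign changes exist the smallest root is returned with a
  warning; if none exists a typed outcome distinguishes
  "never adsorbs" (ΔF > 0 everywhere) from "always adsorbs" (ΔF < 0).
- Degenerate inputs are typed errors, not NaNs: detached droplets
  (circle missing the plane), collinear circle fits, non-monotone
  separation grids, non-integrable tails, NaN cells in tables (reported
  with row/column).
- Profile rows outside the solubility limit or with a collapsed
  threshold (cos argument > 1) are flagged in a `flag` column rather than
  dropped, so downstream plots can show where the model degrades.

## Known limitations

- The linear w_sl(θ) law is calibrated on one substrate family; strongly
  charged or highly polarizable surfaces (metals) violate the
  dispersion-dominated assumption.
- The adhesion-tension line is an ansatz; real mixtures deviate near
  neat water for some substrates (off-trend points can be excluded from
  fits via the mask, mirroring how such outliers are handled in
  practice).
- The droplet module is strictly 2-D (cylindrical caps); spherical-cap
  analysis with line tension is out of scope.
- No trajectory processing: density maps and pressure–distance curves
  are expected from upstream simulation tools.
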