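# monowet

Wetting thermodynamics of surface-adsorbed lipid monolayers.

Lipid coatings — single monolayers adsorbed tails-down on a solid — matter
for colloidal stabilization, antifouling and biosensor surfaces, yet
whether a given substrate holds a stable monolayer at all is decided by a
competition that is easy to state and awkward to measure: is the adsorbed
monolayer lower in free energy than the lipid bilayer it would otherwise
form in bulk solution?  `monowet` implements the two-state model that
answers this from a single substrate descriptor, the water contact angle
θ, together with the two simulation post-processing steps that supply the
model's inputs.  It is aimed at people analyzing molecular-dynamics
simulations of supported lipid films and at experimentalists who want the
desk-scale thermodynamics without the simulations.

## The model

Per unit monolayer area, the free energy of adsorbing a monolayer from a
bulk bilayer onto a substrate with water contact angle θ is

```
ΔF/A = w_ll/2 − w_sl(θ) + γ·cos θ        [mN/m]
```

where `w_ll` is the work of adhesion of the two bilayer leaflets across
vacuum (49 mN/m for DLPC), `w_sl(θ)` the substrate–lipid work of adhesion
(weakly linear in θ: 57 mN/m at θ = 0° to 52 mN/m at θ = 113°), and
`γ·cos θ` the adhesion tension of the solvent that must be removed from
the substrate (Young's equation).  The **adsorption contact angle**
θ_ads is the root ΔF(θ_ads) = 0, equivalently the fixed point

```
cos θ_ads = (2·w_sl(θ_ads) − w_ll) / (2γ);
```

substrates with θ > θ_ads are coated by a monolayer, more hydrophilic
ones keep the bilayer.  The package also covers the air–water interface
(θ = 180°, w_sl = 0, so ΔF_air/A = w_ll/2 − γ), the hydrocarbon-liquid
estimate cos θ_ads ≈ γ_hc/γ, and solvent exchange in water/alcohol
mixtures through a Zisman-type adhesion-tension line
γ·cos θ = c0 + c1·γ anchored at neat water and the neat organic, whose
slope vanishes at the critical angle cos θ_wc = γ_alc/γ_w.

Two MD post-processing procedures feed the model: contact angles of
sessile *cylindrical* droplets extracted from time-averaged 2-D density
maps (iso-density contour → circle fit → angle at the substrate plane →
1/R extrapolation to the macroscopic limit), and works of adhesion from
pressure–distance curves (trapezoid integration with an analytic
power-law tail, bar·nm → mN/m).  A seeded synthetic-data module generates
all of these inputs with known ground truth.

## Worked example

```python
>>> import monowet as mw
>>> mw.solve_adsorption_angle()            # default DLPC/SAM model, water
65.73279455006123
>>> mw.adsorption_free_energy(113.0).total # nonpolar substrate: coated
-55.63264125122771
>>> mw.air_water_free_energy()             # Langmuir monolayer forms
-47.5
>>> mw.critical_water_angle(72.0, 22.0)    # ethanol/water slope reversal
72.20840942699236
```

The numbers mean: in neat water the monolayer/bilayer threshold sits at
θ_ads ≈ 66°, so weakly hydrophilic and hydrophobic surfaces get coated; a
nonpolar substrate (θ = 113°) gains 55.6 mN/m of free energy per area on
coating; the air–water interface gains 47.5 mN/m (a Langmuir layer is
favored); and on substrates with θ_w below ≈ 72° adding ethanol weakens
the adhesion tension while above it alcohol strengthens it.

The same computations are scripted as a narrative pipeline in
`analysis/01_water_adsorption.py` … `05_adhesion_work.py`, which write
their tables to `results/`.  A command line mirrors the library:

```
monowet thermo --theta 90
monowet synth --kind droplet --theta 120 --radius 8 --out scratch/demo
monowet droplet --grid scratch/demo/droplet_grid.txt
```

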