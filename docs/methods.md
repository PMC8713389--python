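# Methods

## Physical model

A tetrapolar catheter on the axis of a cylindrical blood cavity of radius
*R* is modelled electrostatically. The drive electrodes are spheres of
radius *r0* at potential ±*V0* located at *z* = ±*d*/2; their equivalent
point-charge strength is *q* = *V0*·*r0* (in V·m, absorbing 1/4πε). The
measurement electrodes sit at *z* = ±*L*/2. Three forward models map *R* to
the measured conductance, each defined by a field, a current integral over
the catheter mid-plane (*z* = 0), and a voltage integral along the axis:

* **wei** — superposition of the two point charges. Current over the
  annulus [*r0*, *R*], voltage over [−*L*/2, +*L*/2]. Evaluating the ratio
  of these integrals gives
  `G = πσ·d·(d²−L²)/(2L)·[1/√(d²+4r0²) − 1/√(d²+4R²)]`.
* **plate** — one sphere (−*Q*) at *z* = +*d*/2 superposed with a uniformly
  charged plate (+*Q*) of radius *R* in the mid-plane. The plate field is
  purely axial, `q·(2/R²)·sgn(z)·(1 − |z|/√(z²+R²))`, taken as uniform over
  the cross-section; it represents the compression of the field into the
  well-conducting blood at the blood–muscle boundary. The voltage is twice
  the axial integral over [0, *L*/2] (the configuration is treated as
  mid-plane symmetric).
* **lead** — reciprocity demands that swapping the injection and
  measurement pairs leaves the measurement unchanged. The two role
  assignments share the same voltage, `V_all = 8·q·L/(d²−L²)`, but the
  two-charge currents for spacings *d* and *L* differ. A multiplicative
  correction with balanced, unit-less factors forces reciprocity and yields
  the geometric mean `G = √(I_d·I_L)/V_all`. The construction is exactly
  symmetric under interchanging the roles.

### Radial reference convention

The mid-plane current integrals of the plate and lead models measure radial
distance from the electrode *surface*: the sphere-field kernel uses
(ρ − *r0*) in place of ρ. The on-axis voltage integrals use the ideal
point-charge field. The Wei model keeps the ideal (axis-referenced) field in
both integrals. This mixed convention is deliberate: it reproduces the
closed-form current and voltage expressions that define the models, and the
quadrature oracle certifies each closed form against the exact field variant
it was derived from. For *r0* ≪ *L*, *d* the two conventions differ by
O((2·r0/(d−L))²), about half a percent at the default geometry.

### Tissue compartments

Current that leaves the blood pool traverses the muscle wall (thickness *b*,
conductivity σ_m) and the background (σ_ba, out to radius *R_ba*). Each
model's total is a sum of per-compartment conductances obtained by moving
the current integral's annulus outward: blood [*r0*, *R*], muscle
[*R*, *R*+*b*], background [*R*+*b*, *R_ba*]. The wei and plate models use
the two-point-charge annulus extension for both tissue terms; the lead model
applies its geometric-mean construction per compartment with the voltage
unchanged. Compartment additivity (`G_total − G_blood − G_muscle −
G_background = 0`) holds exactly by construction.

## Parameters

| parameter | unit | default | rationale |
|---|---|---|---|
| r0 | mm | 1.0 | plausible injection-sphere radius; the validation hardware's geometry is unpublished |
| L | mm | 20.0 | inner (measurement) pair spacing |
| d | mm | 40.0 | outer (injection) pair spacing; must exceed L |
| σ_bl | S/m | per setup | 1.68 / 0.62 (saline series), 0.7 (phantom) |
| σ_m | S/m | 0 | 0.3 conductive wall, 1e−6 insulating silicone, 0 glass |
| σ_ba | S/m | 0 | 0.2 water-tank background for the phantom series |
| b (wall thickness) | mm | 10.0 | not published for the phantom; configurable |
| R_ba (background extent) | mm | 5·d | `None` selects this bounded default; `inf` uses the closed forms' convergent limit (the two differ by <1% at the defaults) |
| V0 | V | 1.0 | cancels in every conductance (ratio of current to voltage) |

Geometry invariants enforced at construction: r0 > 0, 0 < L < d, r0 < L/2.

## Lookup-table inversion

*G(R)* is sampled on a uniform radius grid (default [r0 + 0.5 mm, 80 mm],
2000 points — the upper bound covers severely dilated ventricles). Build
fails, naming the offending interval, if the sampled map is not strictly
increasing. The inverse is evaluated by PCHIP (monotone piecewise-cubic)
interpolation on the (G, R) knots: exact at knots, monotone everywhere.
Round-trip error at 2000 points is below 1e−6 mm for all three models, far
inside the 0.01 mm contract. Conductances outside the table span clamp to
the nearest endpoint radius and are flagged rather than rejected, since
noisy measurements can fall marginally outside.

The plate model's uniform-charge assumption degrades for *R* ≥ *L*; its
blood conductance remains strictly increasing well beyond (it approaches a
finite ceiling), so the library will build tables past the bound and records
a validity warning in the table metadata and estimation results. The CLI
`table` command refuses by default (`--allow-beyond-validity` overrides).
This keeps large-radius fixtures invertible for every model while making
the physical caveat impossible to miss.

## Quadrature oracle

Every closed form is independently certified by adaptive quadrature
(`scipy.integrate.quad`, relative tolerance 1e−10, absolute floor 1e−15 so
near-zero integrals do not spuriously fail): currents as
2πσ·∫E_z(ρ,0)·ρ dρ, voltages as −∫E_z(0,z) dz. When the voltage path
crosses an on-axis point charge (inner-pair injection measured across the
outer pair), the integral is a principal value: the charge's own on-axis
field is exactly q·sgn(z−z0)/(z−z0)², whose principal value over the
segment is elementary, so that component is integrated analytically and the
remaining smooth components numerically. Integration domains otherwise
exclude charge locations for any valid geometry; evaluating a field at a
charge raises. Agreement between closed forms and oracle is at machine
precision (~1e−14 relative) on a 25-point geometry×radius grid per model.

## Synthetic measurements and what they show

The validation study's raw conductance recordings are unpublished, so the
fixture generator replays its *conditions*, not its data: five glass
cylinders (radii 13.3, 17.5, 32.8, 38.6, 50.4 mm; saline 1.68 or 0.62 S/m;
insulating wall and surround) and six ventricle-phantom filling steps whose
reference radii are the equivalent circular radii √(A/π) of the published
cross-sections (19.94 down to 11.30 mm; σ_bl = 0.7, σ_ba = 0.2, wall either
1e−6 or 0.3 S/m). Synthetic conductances are the forward model value times
(1 + ε), ε Gaussian with configurable relative SD (default 2%, a typical
impedance-analyzer noise scale; noise proportional to signal because such
instruments' error is predominantly multiplicative).

Consequences for interpretation:

* Zero-noise closed loops (simulate with a model, invert with the same
  model) certify the numerical inversion machinery — bias and limits of
  agreement below 1e−7% — not the physical fidelity of any model.
* Cross-model runs (lead-generated conductances inverted under the
  classical insulating-Wei assumption) reproduce the *direction* and rough
  scale of the published comparison: the Wei inversion overestimates radius
  by tens of percent in the glass conditions and >100% with a conductive
  surround. The published magnitudes themselves depend on the real
  measurements and hardware geometry and are kept only as documented
  reference constants.
* The generator does not emulate electrode polarization, frequency
  dependence, catheter displacement or deformation of the real phantom, so
  passing tests say nothing about those effects.

## Agreement statistics

Bland–Altman style, matching the validation study's definitions: with
diffs = estimated − reference radii, bias = mean(diffs) and
LOA = 1.96·SD(diffs) (sample SD, n−1), both normalized by the mean
reference radius and expressed in percent.

## Design choices made where the design was open

* The characteristic-table grid bounds and resolution are unspecified
  upstream; [r0+0.5, 80] mm × 2000 was chosen so the round-trip contract
  holds with an order-of-magnitude margin at negligible build cost.
* Conductances are reported as positive magnitudes; the raw field-oriented
  currents and voltages carry signs internally.
* The Wei model accepts tissue compartments (annulus extension) so all
  three models share one breakdown interface; the classical insulating
  variant is the σ_m = σ_ba = 0 case.
* Table CSVs omit the in-memory build timestamp so identical runs produce
  byte-identical files; floats are serialized with full round-trip
  precision.
* Problem sizes in the test-suite and acceptance script (grid points,
  fixtures × repeats, 50 reciprocity geometries, 100 round-trip radii)
  were chosen as the smallest sets that exercise every certified property;
  all of them run in seconds.

## Known limitations

* Purely electrostatic, axisymmetric, concentric-cylinder geometry; no
  frequency-dependent (complex) impedance, no electrode polarization, no
  off-axis or tilted catheter.
* The plate model underestimates large radii by construction (uniform plate
  charge); treat `R ≥ L` results as extrapolation.
* The refraction boundary condition motivates the plate construction but is
  not solved exactly; no full 3-D boundary-value solution is attempted.
* Tissue compartments are concentric annuli with sharp interfaces and a
  single wall thickness; real ventricular walls are neither uniform nor
  concentric.
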