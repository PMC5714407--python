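# Methods

## Model

### Geometry

A 30 × 30 × 30 cm³ liquid-water cube surrounded by vacuum, with the source
at the coordinate origin and its long axis along z. Configurations are
labelled by the water thickness on either side of the source along the
shift axis:

* `(15, 15)` — centred source, full scatter;
* `H(30−x, x)` — cube shifted along −x so only x cm of water lies beyond
  the source on the +x ("toward") side, transverse to the source axis;
* `V(30−x, x)` — the same along the source axis.

The missing-tissue thickness is 15 − x cm. Photons crossing any cube face
enter vacuum and never return; this is the entire missing-scatter
mechanism. No applicator, encapsulation, or tissue heterogeneity is
modelled.

### Sources

* **103Pd**: 0.455 cm active line; K x-ray and gamma line spectrum, mean
  ≈ 20.7 keV; 5 keV transport cutoff.
* **192Ir**: 0.5 cm active line; 24-line gamma/x-ray spectrum (the strong
  296–468 keV gammas dominate); 10 keV cutoff.
* **137Cs**: a 2.5 mm pellet train. The default arrangement `NANAANAN`
  (A = active, N = inactive) puts four active pellets at z = ±0.625 and
  ±0.125 cm, spanning 1.5 cm, which is also the active length used in the
  geometry function; `AAAAAA` is available. Single 661.7 keV line; 10 keV
  cutoff.

Spectra are normalised to one emitted photon per history; absolute
intensities cancel in every ratio the package reports. Emission is uniform
along the active line (or uniform over active pellet centres) and
isotropic.

### Interaction data

Mass attenuation (μ/ρ) and mass energy-absorption (μen/ρ) coefficients for
liquid water and dry air were transcribed by hand onto a 28-point grid from
1 keV to 2 MeV and interpolated log-log (exact for power-law behaviour
between nodes). Interaction-channel fractions at each node were
apportioned consistently with the total: the incoherent part follows the
free-electron Klein–Nishina cross section with a smooth low-energy
binding-suppression factor, the photoelectric part is reconstructed from
the energy-absorption column minus the incoherent energy-transfer
contribution, and the coherent part is the residual. Absolute agreement
with any particular production cross-section library is not claimed; the
package's estimands are ratios of doses computed with the same data, which
are insensitive at this level (see Limitations).

### Transport and scoring

Analog photon transport under the kerma approximation:

* free paths are exponential with the local total attenuation coefficient;
* photoelectric absorption terminates the history (electrons are not
  transported — their range is ≤ a few mm at these energies, small against
  the 0.5–6 mm tally cells and the centimetre length scales of interest);
* Compton scattering is sampled from the free-electron Klein–Nishina
  distribution with Kahn's rejection method, azimuth uniform;
* coherent (Rayleigh) scattering uses the Thomson angular law (no atomic
  form factor) and can be toggled off, in which case coherent events are
  treated as undeflected;
* collision kerma is scored with a track-length estimator in spherical
  cells: each flight segment contributes (chord length) × E × μen(E)/ρ,
  divided by the cell volume, giving dose per emitted photon. The final
  straight flight of an escaping photon is extended ~100 cm through the
  surrounding vacuum and still scored, so cells on or just inside a phantom
  face (e.g. the r = 5 cm toward-side cell of `H(25, 5)`, which sits
  exactly on the face) receive the correct outgoing-fluence kerma.
* tally cells whose centres fall outside the (closed) cube are masked and
  reported as NaN, matching the blank entries of bounded-phantom dose
  tables.

Tally radii ramp linearly with r from 0.5 mm to 6 mm. The reference
experiment used 0.2–0.7 mm cells at ~10⁹ histories; at desk-scale history
counts those would starve statistically, and the g(r) and PF(r) ratio
estimands are insensitive to cell size at these scales.

### Randomness and correlated sampling

A counter-based scheme derives an independent xorshift128+ substream from
(seed, history index) via splitmix64 hashing. Results are therefore
bit-reproducible, independent of batching, and — crucially — two runs with
the same seed but different phantom shifts reuse identical emission and
interaction random numbers. Perturbation-factor ratios between such runs
are strongly positively correlated: at 10⁶ histories the 137Cs PF(5 cm)
seed-to-seed spread is ~0.002, an order of magnitude below the quoted
uncorrelated error bars.

### Air-kerma strength

S_K is estimated in a void world with dry-air kerma cells on the transverse
axis at 0.5–25 cm. Each distance d yields kerma(d)/G_L(d, π/2); the
far-field estimates (d ≥ 5 cm) are combined by inverse-variance weighting,
with a reduced-χ² flatness warning. Since dose tables are normalised per
unit S_K and g(r), F(r, θ), and PF(r) are all internally normalised, S_K
precision only affects the dose rate constant.

### TG-43 extraction

With the reference point at r₀ = 1 cm, θ₀ = 90°:

* G_L(r, θ) = β / (L·r·sin θ), with the (r² − L²/4)⁻¹ branch on the axis
  and 1/r² for point sources. β is built from arctan2 of the exact
  cross/dot products of the tip vectors, which is numerically stable near
  the line extension.
* g_L(r) = [D(r, 90°)/D(r₀, 90°)] · [G_L(r₀, 90°)/G_L(r, 90°)], normalised
  exactly at the tabulated reference sample; interpolated log-linearly in r.
* F(r, θ) = [D(r, θ)/D(r, 90°)] · [G_L(r, 90°)/G_L(r, θ)]; masked points
  propagate, and bilinear interpolation refuses blocks touching a masked
  corner.
* Λ = D(r₀, 90°)/S_K, averaging both sides' reference samples.
* The two sides of the shift axis are carried as an explicit
  `toward`/`away` tag rather than extending θ beyond 180°.

### Perturbation factors and corrections

PF(r, x) = g_shifted(r)/g_full(r); the correction is its exact inverse,
g_shifted = PF · g_full. Fifteen published degree-≤6 polynomial fits of
PF(r) (three isotopes × five overlying thicknesses from 2 to 8 cm) ship as
packaged data. `fit_polynomial` performs least-squares fits with automatic
degree selection (smallest degree whose residual RMS is within 10% of the
next degree's).

Percent differences follow the three conventions of the published tables:
`sides` = 100(away − toward)/away, `vs_full` = 100(full − shifted)/full,
`vs_shifted` = 100|full − shifted|/shifted.

## Synthetic data scope

`synthetic` exists for validation plumbing, not physics:

* analytic per-isotope g(r) models (linear for 137Cs, quadratic for 192Ir,
  exponential for 103Pd) multiplied by the line-source geometry function,
  an anisotropy model, an optional injected PF on the toward side, and
  multiplicative Gaussian noise with σ(r) = σ₁₀ · r/10 (independent across
  cells; tally correlations are not emulated). The models are loosely
  calibrated to the published full-scatter columns so closed-loop recovery
  tests are non-trivial.
* the published reference tables (transverse-shift g columns, longitudinal-
  shift g columns, dose-rate constants, 5-cm g-ratios) as literal fixtures
  for exact regression of the report arithmetic.

## Numerical choices

* Log-log interpolation for μ/ρ and μen/ρ; linear-in-log-energy for channel
  fractions, renormalised to sum to one.
* Channel selection uses cumulative fractions with draws on [0, 1) and
  boundary ties assigned to the upper channel.
* Polynomial evaluation raises outside each fit's validity range
  [0.25 cm, x]: beyond the overlying thickness x the toward-side point is
  outside the phantom and the published coefficients diverge.
* 53-bit uniforms; Kahn's method for Klein–Nishina; direction rotation
  renormalises and switches to a stable branch near the poles.
* Per-history batch statistics (sum, sum of squares, hit count) give the
  standard error of each tally mean.

## Limitations

* Simplified interaction data: hand-transcribed coarse grids, free-electron
  Compton (no Doppler broadening or binding beyond a suppression factor),
  Thomson-law coherent scattering, no fluorescence after photoelectric
  absorption, no electron transport. Absolute doses and dose-rate constants
  are therefore **not** benchmark quality; the package's validated outputs
  are internally normalised ratios (g, F, PF, percent differences), where
  these approximations largely cancel. The Monte Carlo 137Cs 5-cm-overlying
  g-ratio at r = 5 cm lands within ±0.02 of the published 0.95; its small
  positive bias (~+0.01) is consistent with the simplified coherent and
  low-energy physics.
* Simplified source geometry: bare line/pellet emitters without capsules;
  near-field anisotropy is approximate.
* Desk-scale statistics: default runs use 10⁵–10⁷ histories against ~10⁹ in
  the reference experiment. 103Pd is the worst case — its ~21 keV photons
  barely reach r = 5 cm, so resolving its perturbation factor there needs
  tens of millions of histories. The relative perturbation ordering of
  103Pd vs 137Cs at r = 5 cm is below desk-scale resolution.
* One published 137Cs coefficient row, `(24+6)`, is internally inconsistent
  (it goes negative inside its own validity range). It ships verbatim for
  transcription fidelity but is excluded from sanity property tests; the
  separately published 103Pd `(25+5)` 5-cm ratio (0.91) also disagrees with
  its own polynomial (≈0.95), so 103Pd is excluded from the polynomial
  consistency check.
* Every empirical claim above is computed by the test suite or
  `scripts/acceptance.py`; no further accuracy is asserted.
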