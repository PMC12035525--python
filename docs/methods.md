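# Methods

This note records the models implemented in `lianaspec`, their assumptions,
the numerical choices behind them, and what the synthetic-data defaults do
and do not emulate.

## Leaf model

The leaf is a pile of `N` semitransparent plates separated by air spaces
(`N ≥ 1`, real-valued; it tracks the number of air–cell-wall interfaces and
correlates with leaf thickness). Per-plate absorption is
`k(λ) = Σᵢ cᵢ·sacᵢ(λ) / N`, a concentration-weighted sum of the
constituents' specific absorption coefficients: chlorophylls `C_ab`,
carotenoids `C_ar`, anthocyanins `C_an` (variant "D" only), brown pigments
`C_br` (variants "5b" and "D"), water `C_w` (g/cm², the equivalent water
thickness) and dry matter `C_m` (g/cm²). Radiation enters the top interface
within a fixed 40° solid angle (a constant, not exposed in configuration);
internal interfaces exchange light isotropically, with interface
transmissivities from Stern's closed-form average and slab transmission
`(1−k)e^{−k} + k²E₁(k)`. The `N`-plate pile is solved with the Stokes
closed form extended to real `N` (eigenstructure of the two-flux transfer
matrix), which the test suite checks against iterative plate stacking
(integer piles) and explicit transfer-matrix fractional powers.

**Coefficient tables.** The bundled refractive index and specific
absorption coefficients are *synthetic*: sums of Gaussian features at the
known band positions (chlorophyll Soret/red bands, anthocyanin green band,
water overtones at 970/1200/1450/1940 nm, dry-matter features at
1720/2100/2300 nm) with realistic magnitudes, generated in code by
`coefficients.default_table`. They reproduce the qualitative optics every
result in the package relies on (red edge, NIR plateau, SWIR water
features) but are not a published empirical calibration; all tests of leaf
optics are therefore invariant- or oracle-based rather than pinned to
literature reflectance values. Users can load an empirical table from
delimited text. The same applies to the bundled soil spectra and the
diffuse-sky fraction table `S(λ, θ_s)` (Rayleigh-like power law plus
aerosol floor, one column per 10° of solar zenith, interpolated).

## Canopy model

Two vertically stacked turbid layers above a Lambertian soil, four streams
(direct solar beam, up/down hemispherical diffuse flux, observer-direction
radiance). The liana layer sits on top with optical thickness
`LAI·L·(1−f₂)`; the host layer carries the remainder, so total leaf area is
conserved and `L = 0` collapses the canopy to a single tree layer (the
implementation returns bit-identical results to a tree-only run in that
case). Each layer has its own leaf optics and a Campbell ellipsoidal leaf
inclination distribution parameterised by its mean angle `Ω`, discretised
into the 13 standard inclination classes (class weights come from a
0.1°-spaced lookup over the mean angle, accurate to ~1e-6, built by
numerical integration of the ellipsoidal density).

Each homogeneous layer is solved in closed form; layers and soil are
combined with the adding method. The implementation was validated to
machine precision against an independent slab discretisation (per-slab
matrix exponentials of the four-stream ODE, 200 sublayers) at hotspot = 0;
that oracle is kept in the test suite at a 1% tolerance.

**Hotspot.** The bidirectional term includes the sun–view gap-correlation
(hotspot) integral with parameter `κ = b/H`, evaluated on a dense geometric
grid that resolves both the correlation scale and the attenuation scale
(the classical 20-point scheme loses a few percent at high LAI).
Correlation is evaluated per layer; the cross-layer term uses the top
layer's joint gap fraction, i.e. the sun–view correlation is not continued
across the layer boundary. This is exact when either layer is empty or
`κ = 0`, and it is why the "identical particles in both layers equals one
layer" identity is asserted at `κ = 0`. Note also that the hotspot term
approaches its dense-canopy asymptote only slowly in LAI (its effective
extinction reduction saturates as 1/LAI); radiative saturation tests
therefore run with the hotspot off.

**Dissociation.** `D = 1` (the default) makes the top layer pure liana
foliage. For `D < 1` each layer's effective leaf optics and mean angle are
linear blends between the fully layered arrangement and the canopy-wide
liana/tree mixture, with liana leaf area conserved. `Cv` is fixed at 1
(closed tropical canopies), which makes the crown-shape parameter `ζ`
inert; open canopies are not supported.

**Sky coupling.** The reported surface reflectance is
`ρ̂ = S·ρ̂_d + (1−S)·ρ̂_s` with the tabulated diffuse fraction `S(λ, θ_s)`
(overridable, including forcing 0 or 1).

## Inversion

The likelihood everywhere is independent Gaussian per wavelength (or per
sensor band after convolution with the spectral response function) with a
single residual standard deviation `σ`, itself a parameter. Sensors with
fewer than 10 bands are refused by default (parameter uncertainty is not
trustworthy at multispectral resolution); an explicit override exists.

* `LeafInversion`: bounded multi-start MAP (5 starts, L-BFGS-B on the
  unit-box-rescaled parameters) is the default path because per-leaf
  inversion is run in bulk; full MCMC is available. Flat priors over the
  physical trait ranges. Non-physical inputs (near-zero spectra) are
  flagged on the results object, not raised.
* `CanopyInversion`: full coupled-chain forward model, sampled with DE-MC:
  3 chains propose jumps along difference vectors of archive states
  (archive seeded from the prior, extended with thinned chain history and
  purged of its prior-seeded head at burn-in end), 20% snooker updates, a
  γ = 1 full-jump every 5th generation for mode exchange, and a jump-length
  multiplier adapted toward ~25% acceptance during burn-in only (the
  post-burn-in kernel is fixed). `fit()` is convergence-targeted: if the
  scale-reduction diagnostic R̂ (computed as `sqrt(1 + B_μ/W)`, exactly 1
  for identical chains) reaches 1.1, the fit is repeated with doubled chain
  length and a derived seed, up to twice; everything is deterministic given
  the input seed. An optional burn-in tempering ramp and DREAM-style
  subspace crossover exist but are off by default (they did not help on
  this model family). Flat priors over physical canopy ranges, with the
  LAI prior capped at 12 because closed-canopy reflectance saturates well
  below the physical ceiling and the flat tail above it is pure
  non-identifiability. `derive_priors` upgrades leaf traits to truncated
  normal priors from leaf-stage summaries (growth-form means/SDs), the
  route by which the leaf stage informs the canopy stage.
* `TraitHierarchy`: `T = μ_growthform + b_species(study) + c_study + ε`,
  Gibbs-sampled with conjugate updates; the growth-form means are drawn
  with the species effects analytically marginalised (a partially collapsed
  step — the centred parameterisation mixes poorly), and all variances
  carry inverse-gamma hyperpriors whose scale is proportional to the sample
  variance so they stay uninformative regardless of the trait's units.
  With a single study the study effect is dropped with a warning. The
  headline output is the liana-minus-tree contrast posterior and its
  zero-overlap fraction `2·min(P(c>0), P(c<0))` — ~0.5 for a null effect
  (verified by calibration simulation), ~0 for a decisive one. The
  hierarchy consumes trait point estimates (e.g. per-leaf MAP fits);
  propagating full per-leaf posteriors is a possible extension.

## Divergence

Spectral ensembles are summarised by per-wavelength mean and SD; the
Gaussian KL divergence is integrated over 400–2500 nm by the trapezoid
rule and reported in nats (optionally per nm). The variance in the
numerator of the middle term is that of the *compared* ensemble — the
standard non-negative Gaussian form, which matches direct quadrature of
the defining integral (the quadrature is retained as an oracle). For
sensor-level divergence the band *means* convolve with the normalised SRF
weights, and the band *spread* convolves linearly by default: ensemble
spread describes canopy-to-canopy variability, which is coherent across
wavelengths and does not average out within a band (independent-noise
propagation with squared weights is available, and is what the inversion
likelihood implies for instrument noise). Band divergences aggregate by
sum ("cumulative", default) or mean.

## Trait-importance experiment

Baseline: a canopy whose top layer carries tree traits throughout.
Reference: the same canopy with liana traits in the top layer. Swapping a
parameter subset replaces those top-layer values with the liana values
(bottom layer stays tree); each configuration defines a spectral
distribution with `μ_λ = ρ̂(λ)` and constant `σ_λ = σ` (the inversion
residual error). Impact = baseline KLD − post-swap KLD, so positive means
"toward the liana signal"; per-wavelength impact curves and VIS/NIR/SWIR
integrals are reported, and two-parameter swaps are decomposed into
additive and interactive components (both the raw pair impact and the
interaction after subtracting single effects are emitted, since either
convention is defensible).

## Scenes and spatial scale

Clustered infestation maps come from thresholding a Gaussian-smoothed
white-noise field at the quantile matching the target prevalence (0.5 by
default); the smoothing length is calibrated by deterministic bisection so
the realised mean connected-component area of the feature phase matches
the target cluster area (350 m² ~ crown infestation, 2,000 m² ~ arrested
gaps, 30,000 m² ~ liana forest). `cluster_area ≤ pixel area` yields
spatially independent pixels (the random-placement baseline).

The divergence-versus-resolution curve is an *expected* KLD: each coarse
footprint mixes the two endmember distributions linearly by its
sub-footprint feature fraction (means mix; the within-footprint spread is
the mixed endmember spread, because the endmember SD represents
canopy-level variability that does not average out across a footprint);
footprints are labelled feature/background by majority rule (an
"any-feature" rule is available); each label group is summarised as a
Gaussian whose variance adds the between-footprint spread of mixture means
to the mean within-footprint variance; and the per-wavelength group KLD is
averaged over wavelength. At native resolution this reduces exactly to the
endmember KLD ("pure signals"). Rendering actual noisy cubes
(`render_scene`, iid draws per pixel) is kept for image simulation; it is
not used for the expected-KLD curves, where iid noise would artificially
shrink group spreads under block averaging.

Default problem sizes: full scenes are 1000×1000 pixels of 1 m². The
acceptance experiments run 200×200 footprints of 5 m covering the same
1 km² extent (the stated cluster areas stay physically meaningful; the
"30 m" comparison is a factor-6 aggregation), 50 replicates per scenario,
with endmember spectra on a 20-nm grid; canopy inversions run on a 10-nm
grid (211 bands, comparable to an airborne hyperspectral sensor). These
sizes are the package's defaults for desk-scale experimentation.

## Synthetic-data defaults

The generator encodes the qualitative liana/tree contrasts as truncated
normal trait distributions (annotated copy in `data/default_traits.yaml`):
liana leaves thinner (N 1.55 vs 1.80), lower pigment (C_ab 35 vs 45
µg/cm²), water (0.009 vs 0.012 g/cm²) and dry matter (0.0075 vs 0.010
g/cm²), and flatter angles (27.9° vs 37.1°, the measured means; population
SD 10°, chosen so that an SE of ~0.7° over ~650–900 leaves back-casts to a
realistic leaf-to-leaf spread). Growth-form trait means sit within one SD
of each other for every leaf trait, mirroring the strong overlap of the
real distributions. Site defaults: LAI 6 ± 1, f₂ 0.66 ± 0.08, soil
moisture 0.5, κ = 0.05, θ_s = 30°, nadir view. Canopy-inversion validation
draws truths from realistic infested-crown ranges (LAI 2–8, liana layer
18–38°, host layer 30–55°, f₂ 0.45–0.85): a liana layer systematically
flatter than its host is the configuration the method targets, and it is
also what keeps the two layers statistically distinguishable — when
Ω₁ ≈ Ω₂ the layers become exchangeable and the posterior irreducibly
multimodal.

**What passing tests do not show.** The generators draw iid Gaussian noise
and iid individuals: no instrument artifacts (smile, striping, noise
floors, atmosphere — deliberately, a best-case analysis), no phylogenetic
or spatial correlation of traits, no topographic or phenological
confounding, and the synthetic coefficient tables mean absolute
reflectance values are only qualitatively realistic. Recovery and ordering
results on this synthetic world demonstrate internal consistency and
calibration of the machinery, not field performance.

## Known limitations

* Open canopies (`Cv < 1`) and crown-shape effects are not implemented.
* The cross-layer hotspot correlation resets at the layer boundary
  (documented above); bidirectional effects near the hotspot are
  approximate for two-layer canopies.
* Heteroscedastic residual models are out of scope (single σ across
  wavelengths).
* The hierarchical stage consumes point estimates, not per-leaf
  posteriors.
* Canopy posteriors can be genuinely multimodal when the two layers are
  near-exchangeable; the convergence-targeted refit reports honest
  diagnostics but cannot make an unidentifiable configuration identifiable.
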