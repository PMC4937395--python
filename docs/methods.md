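# Methods

`hazecrop` estimates how severe aerosol pollution over China's four major
polluted crop regions — the North China Plain (NCP), Yangtze River Delta
(YRD), central eastern China (CEC) and Sichuan Basin (SCB) — reduces the
solar radiation reaching the surface, and how that translates into rice and
wheat production losses. This note records the model chain, the defaults
and why they were chosen, the numerical choices, and what the synthetic
data do and do not establish.

## Synthetic AOD fields

The analysis was designed for a two-year satellite record of monthly
550 nm aerosol optical depth (AOD) at 0.1°. Because no such record ships
with the package, `synthetic_data` generates fields with the same
statistical structure:

* inside the four region boxes, AOD is drawn uniformly from 0.4–0.8 (the
  observed hotspot range) and modulated by a multiplicative seasonal cycle
  `1 + a·cos(2π(m−1)/12)` peaking in January (default amplitude a = 0.3,
  standing in for winter heating emissions);
* background cells are Gaussian around 0.1 (s.d. 0.02, clipped at 0);
* a configurable fraction of cells (default 0.3) is flagged missing
  uniformly at random, emulating cloud/bright-surface retrieval gaps;
* 25 monthly fields (April of year 1 through April of year 3) by default.

Region boxes default to NCP 113–120°E/34–41°N, YRD 117–122°E/29–34°N,
CEC 110–117°E/26–32°N, SCB 103–108°E/28–32°N (half-open, hence disjoint);
published maps outline the regions without coordinates, so these are
approximations and fully overridable.

What the generator does **not** emulate: spatial autocorrelation, partial
hotspot coverage inside the region outlines, spatially structured
missingness, or inter-annual trends. The most important consequence is
that *every* region cell sits at hotspot level, so regional reduction
statistics land near the upper end of what heterogeneous real fields
produce: the synthetic pooled winter interquartile range is ≈38–42%,
comparable to the observed *maximum* reductions (28–49%) rather than to
the observed all-region interquartile band (11–29%). Passing tests on
synthetic data therefore validate the machinery and the physics, not the
spatial statistics of any particular year's satellite record.

## AOD processing

Fields are block-averaged from 0.1° to 0.5° (factor 5). Each coarse cell
is the arithmetic mean of its unmasked fine members (`np.nanmean` over the
25-member block, bitwise reproducible by a per-block loop); a coarse cell
is masked only when all members are missing, with a minimum-valid-fraction
threshold exposed for stricter screening. No cos-latitude weighting is
applied inside a 0.5° block (negligible at this scale). Calendar-month
climatologies average unmasked values across years; seasonal means average
the three member months (DJF/MAM/JJA/SON).

## Radiative transfer

Cloud-free surface spectral irradiance over 300–750 nm (a proxy for
photosynthetically active radiation) is computed with a delta-Eddington
two-stream solver written for this package:

* **Column.** 13 layers from the surface to 50 km. Aerosol is well mixed
  below the boundary-layer top (default 1 km) and decays exponentially
  above (scale 1.5 km), continuous at the interface. Spectral AOD follows
  the Ångström law `AOD(λ) = AOD₅₅₀·(λ/550)^−α` with α = 1.0 by default
  (the gridded AOD is treated as the 550 nm value). Aerosol
  single-scattering albedo is 0.80 and the surface albedo 0.2 — the
  scenario values of the analysis; the asymmetry parameter defaults to
  0.65 (typical continental aerosol). Rayleigh scattering uses the
  Hansen–Travis λ⁻⁴ parameterization distributed with an 8 km pressure
  scale height; ozone (default 300 DU) uses a coarse embedded
  cross-section table (Huggins edge + Chappuis band) placed at 15–35 km.
  The ozone table is approximate; it enters both the baseline and the
  perturbed run, so it largely cancels in the reduction ratio.
* **Solver.** Per layer, delta scaling (f = g², τ′ = (1−ωf)τ,
  ω′ = (1−f)ω/(1−ωf), g′ = g/(1+g)) followed by the closed-form Eddington
  two-stream solution for diffuse reflectance/transmittance and the
  beam-source fluxes; layers are combined top-down by the adding method
  with a Lambertian floor. The adding recursion is the exact solution of
  the multilayer two-stream boundary-value problem (verified against a
  direct numerical BVP integration to 1e-15, and by exact invariance under
  sublayer splitting). The reported direct beam is the unscaled
  Beer–Lambert transmission `exp(−τ/μ₀)`; the delta-scaled forward spike
  is counted as diffuse, so global = direct + diffuse holds exactly.
* **Numerical guards.** ω is capped at 1−1e-9 (the conservative limit is
  approached, not hit, keeping the closed forms finite while conserving
  energy to ~1e-8); the beam-resonance denominator (λμ₀ → 1) is clamped at
  1e-4, leaving the benign cancellation between particular and homogeneous
  terms at round-off level; diffuse fluxes are floored at 0 (the Eddington
  approximation can produce ulp-scale negative reflectances at very low
  ω).
* **Accuracy.** Against an independent 10⁶-photon Monte-Carlo transport
  oracle (Henyey–Greenstein phase function, Lambertian floor, itself
  verified against an exact source-iteration solution of the radiative
  transfer equation), global surface fluxes agree to ≲1% in the hazy-sky
  regime that dominates this analysis (ω ≥ 0.85, τ ≲ 1.5, μ₀ ≥ 0.7). As
  for every two-stream scheme, errors grow in strongly absorbing, thick,
  slant-sun conditions: up to ~4% at τ = 2, ω = 0.8, μ₀ = 0.866 and ~9% at
  μ₀ = 0.5. This is an inherent limit of the Eddington closure (quadrature
  and hemispheric-mean coefficient sets measured no better), and is a known
  limitation of the package.
* **Spectrum and diurnal cycle.** The extraterrestrial spectrum is a
  synthetic smooth surrogate — a 5772 K blackbody scaled to the 1361 W m⁻²
  solar constant. All quantities of interest are irradiance *ratios*,
  which are exactly invariant to the spectrum's absolute scale (asserted
  in tests), and insensitive to its fine structure. Each month is
  represented by its 15th day; daily means are midpoint quadrature over 24
  daylight hour-angle nodes, expressed as W m⁻² averaged over the 24 h day.
  The default wavelength grid is 1 nm from 300 to 750 nm.

## Solar reduction

For each unmasked 0.5° cell and month the solver runs twice — aerosol-free
(E₀) and with the cell's AOD (E_a) — and the reduction is
100·(E₀−E_a)/E₀; the baseline depends only on latitude and month and is
cached. Regional statistics are quartiles (linear interpolation between
closest ranks) over unmasked region cells; seasonal statistics pool the
cell values of the three member months (not means of means); a pooled
all-four-regions row is emitted alongside the per-region rows, since the
published presentation is ambiguous between the two. The growing-window
reduction for a crop is the arithmetic mean over the three calendar months
immediately preceding its harvest month (wrapping across the year
boundary), e.g. a June wheat harvest uses March–May.

## Crop impact

* **Yield response.** Linear: percent yield loss = β · percent loss of
  effective radiation, clipped to [0, 100]. Only paired percentages are
  recoverable from the published record, so β is calibrated per crop by a
  through-origin least-squares fit of the published regional yield losses
  (wheat 10/13/11/14%, rice 6/6/3/4% for NCP/YRD/CEC/SCB) on the
  growing-window reductions of the default synthetic run
  (`scripts/calibrate_beta.py`, seed 0). The defaults are β_wheat = 0.4267
  and β_rice = 0.2189 with maximum residuals of ~2 percentage points
  (reported by the script, not hidden). Harvest months are provincial:
  within the NCP, Henan/Shandong wheat is cut in June but Hebei in August,
  so windows are evaluated per province over the region's cells and
  production-weighted to the region.
* **Diffuse-radiation cases.** Canopies use diffuse light more efficiently
  than direct light, so effective photosynthetic radiation is
  P = E_dir + k·E_dif with k ≥ 1; the percent change of P replaces the
  plain global reduction. k = 1 reproduces the unadjusted pipeline
  bit-for-bit. The low/moderate/high cases default to k = 1.15/1.3/1.5,
  graded so the high case roughly halves the national losses under the
  default radiation fields (≈0.85×/0.7×/0.5×), consistent with the
  published high-diffuse outcomes (wheat 8→4.5%, rice 2→1%); they are
  declared surrogates for an unpublished parameterization and are fully
  config-exposed. A negative effective change (diffuse gain exceeding the
  total loss) is reported, logged, and floored at 0 before the yield model.
* **Thick cloud.** Under optically thick cloud the marginal aerosol effect
  on surface radiation vanishes, so the aerosol-attributable loss is
  damped linearly by the thick-cloud fraction (default 0.25, chosen so the
  damped high-diffuse wheat loss ≈ 3.2–3.4%).
* **Aggregation.** National percent loss = Σ_regions (regional yield loss ×
  regional production share); tonnes = percent × national production/100.
  Default national totals (2.5×10⁸ t wheat, 2.95×10⁸ t rice) make the
  published absolute and percent losses mutually consistent. Regional
  shares default to wheat NCP 47%, YRD 19%, CEC 5%, SCB 4% (four-region
  total 75%) and rice NCP 3%, YRD 15%, CEC 20%, SCB 7% (total 45%); the
  NCP rice and the CEC/SCB wheat splits are not individually published and
  are stand-ins constrained by the published totals. Four-region averages
  are emitted both production-weighted and unweighted (the published
  averages, 11% wheat and 4% rice, are closer to the weighted ones).
  Display rounding follows the published style: one decimal below 5%,
  integer above; raw floats are always retained in machine output.

## Problem sizes and determinism

The end-to-end default run (25 synthetic months at 0.1°, regridded to
0.5°, radiation computed over the ~544 four-region cells × 12 climatology
months at 1 nm/24 nodes) completes in about a minute on one core; this is
the size used by the test suite and the acceptance script. All randomness
(field generation, production-table jitter, Monte-Carlo oracle) flows
through explicit integer seeds; regeneration is bit-reproducible.

## Known limitations

* Two-stream flux accuracy degrades in absorbing/thick/slant-sun corners
  (numbers above); a multi-stream discrete-ordinates solver is out of scope.
* The linear β response and the k-multiplier diffuse model are declared
  surrogates for unpublished empirical relationships; both are calibrated,
  not derived.
* The synthetic fields saturate regions at hotspot AOD, biasing regional
  reduction statistics high relative to heterogeneous observed fields.
* NetCDF output uses the NetCDF-3 classic format (scipy backend).
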