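# Methods

This note documents the models behind `driftquant`, the defaults and why
they were chosen, the numerical decisions, and what the synthetic-data
generator does and does not emulate.

## Larval drift model

The drift stage is a Lagrangian individual-based model. Each particle is a
larva with position (lon, lat, depth), length, hatch time and a status in
{active, beached, exited}.

**Release.** Particles are split across named spawning grounds by fixed
fractions (defaults 50/20/10/20 % for the Møre, Haltenbanken, Sklinna and
Røst grounds, south to north along the Norwegian coast). Integer counts use
largest-remainder rounding so the grand total is exact. Hatch times follow
a Gaussian intensity truncated to the hatch window (default 15 March–20
April). Only the window is prescribed by the study system; the Gaussian
parameters are this package's choice: mean at the window midpoint and
standard deviation of one sixth of the window length (≈ 6.2 days), so the
window covers ±3 σ and the intensity falls essentially to zero at both
edges. Releases at a point can be jittered within a radius or spread
uniformly over a polygon (rejection sampling via shapely).

**Advection.** Horizontal positions are integrated with classical RK4 at a
default step of 3600 s over velocities interpolated trilinearly in
(depth, lat, lon) and linearly in time between daily-mean fields. Degrees
and metres are converted with the spherical metric (cos φ in longitude,
R = 6371 km). Daily-mean forcing cannot justify a fancier scheme; RK4 at
1 h is cheap and its truncation error is negligible against the forcing
resolution (the solid-body-rotation test closes an orbit to ~2 × 10⁻⁶ of
its radius). Vertical currents are never applied to particles: vertical
motion is entirely behavioral.

**Vertical behavior.** Larvae migrate between a 5 m night depth and a 40 m
day depth, moving toward the current target at 0.1 body lengths s⁻¹ and
clamped to the band. The swim speed is attached to the migration and not
used horizontally. Day/night comes from geometric solar elevation
(NOAA/Meeus low-precision ephemeris, accurate to a few hundredths of a
degree; no atmospheric refraction, which would shift the terminator by
~0.3°, far below what matters for a 35 m depth alternation). At the study
latitudes (to 72° N) the sun does not set near midsummer; there "night" is
defined as ±3 h around the daily solar-elevation minimum, so larvae always
get a shallow phase of roughly the same daily duration. The original
behavior under midnight sun is not documented for this system; this
fallback is the package's own convention and is configurable.

**Growth and status.** Length is L(t) = 9 mm + 0.4 mm d⁻¹ · age, computed
from age rather than accumulated incrementally, so the linear law holds to
machine precision at every step. A particle whose updated position falls on
a land cell (nearest-cell test) is returned to its last wet position and
beached irreversibly; a particle whose RK4 update samples outside the grid
is frozen in place as exited. The particle budget
(active + beached + exited = released) is asserted in tests at every
snapshot.

**Densities.** Snapshots are binned on half-open lon/lat cells
(`numpy.histogram2d` convention). Display transforms: raw counts,
log(n + 1) (defined at empty cells) and √n.

## ddPCR quantification

A well with n⁺ positive of N accepted droplets gives the Poisson
occupancy estimate λ = −ln(1 − n⁺/N) copies per droplet and a reaction
concentration λ/v_d. The droplet volume v_d defaults to 0.85 nL, the
QX200 convention; it is configurable because instruments differ and the
protocol does not pin it.

Normalisation to gene copies per gram of stomach content multiplies the
reaction concentration by the template dilution factor (reaction volume /
template volume = 22/5.5 = 4), the sample dilution (1, 10, 40 or 100), and
the elution volume (default 150 µL, the midpoint of the 100–200 µL
protocol range, used when per-sample volumes were not recorded), then
divides by tissue mass. Tissue mass is wet weight / (1 + PBS ratio) with
the default 1:3 homogenisation ratio, treating buffer volumes as
weight-equivalent (density ≈ 1 g mL⁻¹). Visually empty stomachs carry a
nominal 0.01 g so a per-gram value remains defined; their results should
be read as "residual DNA signal", not a concentration in food.

Replicate subsamples (five per stomach by design) are averaged
arithmetically on the copies-per-gram scale. Below-detection replicates
(zero positive droplets in a well with many droplets) enter the mean as
zero and are flagged; excluding them instead is a config option. "No call"
wells (no accepted droplets) are a data error, distinct from true
negatives.

QC rules: accepted-droplet counts outside [13,000, 21,000] flag the well
for repetition (boundaries inclusive as passes). Fewer than 30 negative
droplets means the Poisson inversion is on its steep tail; the estimate is
computed at that threshold and flagged saturated — a lower bound, matching
the protocol's response of re-running at higher dilution. Any
no-template/negative control or blank with more than 2 positive droplets
marks the run contamination-suspect; a positive control with zero
positives voids the run.

### In-silico PCR

Primer matching is IUPAC-aware on both primer and reference (bitmask
intersection of base sets), with a per-primer mismatch budget (default 0)
and a product length cap (default 2,000 nt). Both strands are searched and
minus-strand products are mapped back to forward coordinates. Amplicon
length includes both primer footprints, so the bundled herring assay
(17 nt forward, 22 nt reverse, 30 nt insert) yields 69 bp. The bundled
reference for offline verification is *synthetic* — random flanks around
the exact primer sites and a fixed insert — because the true mitogenome
is not shipped with the package; it exercises the matcher, not herring
biology.

## Survey statistics

Gene-copy responses are analysed as log₁₀(x + 1). The raw scale is
heavily right-skewed (lognormal-like station and fish effects) and
contains true zeros, so the +1 offset keeps below-detection stomachs in
the analysis; the base-10 choice only rescales F and changes no test.

The one-way station ANOVA is the classical fixed-effects decomposition;
stations with fewer than two stomachs are excluded with a warning, and a
response with zero variance is an error rather than F = ∞. Tukey HSD
p-values are computed directly from the studentized-range distribution
(`scipy.stats.studentized_range`), with the Tukey–Kramer harmonic
correction for unbalanced stations. This keeps the two-group identity
(Tukey p = ANOVA p) exact to numerical precision, which table-interpolated
implementations cannot guarantee; the statsmodels implementation serves as
an independent cross-check in the test suite. Residual diagnostics
(Shapiro–Wilk, Levene) are attached, and outliers are diagnosed — via
studentized-range, leverage and the hat-matrix trace identity Σhᵢ = 2 —
but never dropped.

Pearson correlations report r, t = r√(n−2)/√(1−r²), df = n−2 and the
two-sided p; a permutation null is the oracle in tests. Leverage for the
visual-vs-molecular regression is hᵢ = 1/n + (xᵢ−x̄)²/Σ(xⱼ−x̄)², flagged
above 2·(2/n); a single stomach stuffed with identifiable larvae can
otherwise dominate the fitted line. Schoener's D = 1 − ½Σ|pᵢ−qᵢ| on
normalised distributions is provided in the overlap table as an extension
beyond the core analysis.

A vectorised Monte-Carlo helper (`simulate_anova_rejection_rate`)
estimates the ANOVA's type-I error and power under the lognormal
station-effect model; the test suite requires type-I ∈ [0.03, 0.07] at
α = 0.05 over 2,000 simulated surveys and power > 0.9 under a 10-fold
(σ = 0.5 log₁₀) station effect with 10 stations × 8 fish.

## Synthetic data: what it emulates and what it does not

**Flow fields.** A northward coastal jet with Gaussian cross-shore profile
(core speed default 0.30 m s⁻¹, within the 0.15–0.40 m s⁻¹ band typical of
the Norwegian Coastal Current; everything capped at 1.0 m s⁻¹), optional
eddies from Gaussian streamfunctions, and a straight-coastline land mask.
Eddy velocities are the centred-difference curl of the streamfunction on a
fixed-latitude metric, which makes the discrete horizontal divergence
cancel exactly in the interior — the property the tests check. Not
emulated: topographic steering, sigma-coordinate bathymetry, wind-driven
variability, vertical shear. A passing drift test therefore shows the
integrator and behavior rules are correct, not that trajectories match any
specific year's hindcast.

**Droplet data.** Wells are simulated either from the binomial partition
law (each droplet positive with probability 1 − e^−λ) or by brute force:
the number of template molecules is drawn Poisson(λN) and the molecules
are placed uniformly into droplets. The Poisson molecule count makes the
brute-force model exactly the independent-Poisson partition law, so the
two modes agree in distribution and the second is a genuine independent
oracle for the first. A fixed molecule count (round(λN)) is also available
but is underdispersed relative to the partition law — measurably so at
N = 20,000 — and is kept only for sensitivity analysis.

**Stomach surveys.** Two cruise years (11 and 9 stations), up to ten fish
per trawl, five replicate subsamples per stomach. Signal structure is
lognormal throughout: a per-station effect (σ = 0.5 log₁₀ units), fish
scatter (σ = 0.5) and replicate scatter (σ = 0.2). The fish and replicate
scales are conventions — the field data report only that variability was
high — and are exposed in `ScenarioConfig`. A base level of 10^6.5
copies/g sits inside the observed field range. Droplet counts are
generated through the *inverse* of the normalisation chain with the
smallest protocol dilution (1/10/40/100) that keeps occupancy below
saturation, so the quantification stage can recover the configured signal;
the `truth` table records both the fish-level signal and the DNA actually
present in the drawn subsamples (the estimand of the assay). Empty
stomachs occur with probability 0.07 (matching the handful observed per
survey) and keep a residual 10⁻³ of the fish-level signal, emulating
detectable DNA in visually empty stomachs. Visual counts are Poisson with
a saturating mean in the true signal — qualitative, deliberately not
fitted to any observed counts. Trawl densities are drawn log-uniformly
over the observed 39–13,230 kg NM⁻² range; plankton stations include one
patch station above 50 larvae per 10 m³.

Not emulated: digestion kinetics (the mapping from larvae eaten to gene
copies), otolith retention, spatial autocorrelation between neighbouring
stations, and any linkage between the drift simulation's larval field and
the stomach signal. Recovery tests therefore validate the measurement and
inference chain, not trophic dynamics.

## Numerical and design choices

- Time is UTC throughout; longitudes east-positive; depth positive down.
- Interpolation clamps depth and time queries to the grid span (daily
  means are held constant beyond the axis ends); horizontal queries
  outside the grid return NaN, which the stepper converts to exited.
- Length-1 grid axes are padded by duplication so linear interpolation is
  defined on degenerate (e.g. single-depth) fields.
- Binned cells are half-open with the lower edge inclusive; the last cell
  includes its upper edge (numpy convention).
- CSV IO writes floats at 17 significant digits and reads with
  round-trip parsing, so identical seeds give byte-identical tables.
- Per-ground release counts use largest-remainder rounding; ties go to
  the earlier ground in the configuration order.
- The saturation threshold (30 negative droplets) and the control
  tolerance (2 positive droplets) are conventions, both configurable.
- Seeds: every stochastic entry point takes an explicit seed or
  Generator; the pipeline derives per-stage seeds from one master seed.

## Problem sizes used in the standard checks

The bundled verification runs use 5,000 particles over 60 days for the
drift invariants, 10,000 draws for the hatch-time distribution test, 200
wells per occupancy level for estimator recovery, 2,000/500 simulated
surveys for ANOVA calibration/power, and the default two-year survey
(200 stomachs, 1,000 wells) for end-to-end recovery — sizes at which all
Monte-Carlo margins in the tests are comfortable on a single CPU.

## Known limitations

- The drift model has no mortality, feeding, temperature-dependent growth
  or horizontal swimming; it measures transport and exposure, not
  survival.
- Beaching is irreversible and resolution-dependent (nearest-cell land
  test at the grid scale).
- ddPCR estimates assume perfect droplet classification; fluorescence
  thresholding happens upstream of this package.
- The visual-vs-molecular comparison treats visual counts as error-free
  inputs; misidentification is discussed, not modelled.
- Copies-per-gram cannot be converted to larvae eaten without digestion
  and gene-copy-per-larva calibration, which is out of scope.
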