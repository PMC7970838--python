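# driftquant

Tools for locating predation pressure on fish larvae by combining three
lines of evidence: a Lagrangian individual-based model (IBM) of larval
drift, droplet digital PCR (ddPCR) quantification of prey DNA in predator
stomachs, and survey statistics that link predator distribution, larval
density and the molecular predation signal. The package was built around
the study system of Norwegian spring-spawning herring (*Clupea harengus*)
larvae drifting north in the Norwegian Coastal Current while Atlantic
mackerel (*Scomber scombrus*) feed along the drift route, but every stage
is configurable and runs on plain delimited-text and netCDF inputs.

A synthetic-data module generates current fields, droplet tables and
multi-station stomach surveys with the statistical structure the analysis
assumes, so the full pipeline runs and is testable entirely offline.

## What it computes

**Larval drift.** Particles hatch at weighted spawning grounds with a
Gaussian hatching intensity inside a fixed window, are advected by
daily-mean currents (RK4 over trilinear/linear interpolated velocities),
perform diel vertical migration between 5 m (night) and 40 m (day) by
swimming at 0.1 body lengths s⁻¹, and grow linearly, L(t) = 9 mm + 0.4 mm
d⁻¹ · t. Land contact beaches a particle irreversibly; leaving the grid
freezes it as exited. Output: per-day particle snapshots and binned density
grids (raw, log(n+1) or √n).

**ddPCR quantification.** With p the positive-droplet fraction of a well,
the Poisson partition law gives λ = −ln(1 − p) copies per droplet and a
reaction concentration c = λ / v_droplet (v_droplet = 0.85 nL). The
normalisation chain to gene copies per gram of stomach content is

    c × (V_reaction / V_template) × dilution × V_elution / m_tissue,

with m_tissue = wet weight / (1 + PBS ratio), replicate subsamples averaged
arithmetically, and a nominal 0.01 g tissue weight for visually empty
stomachs. QC: wells outside 13,000–21,000 accepted droplets are flagged for
repetition; near-saturated wells (< 30 negative droplets) report a lower
bound; positive droplets in no-template or negative controls mark the run
contamination-suspect. An in-silico PCR module verifies the herring mt16S
assay (69 bp amplicon) against reference sequence, IUPAC-aware with a
configurable mismatch budget.

**Survey statistics.** Larval density as individuals per 10 m³ filtered
water; predator biomass as swept-area density, catch / (distance ×
effective width), in kg NM⁻²; one-way ANOVA with exact Tukey HSD post-hoc
tests on log₁₀(copies + 1) across stations; Pearson correlations of gene
copies against predator covariates with t = r√(n−2)/√(1−r²); hat-matrix
leverage diagnostics for the visual-vs-molecular comparison; and a
per-station overlap table with an optional Schoener's D index.

## Worked example

Quantify one stomach from five replicate ddPCR wells (dilution 1:10,
~0.2 g subsamples homogenised 1:3 in PBS):

```python
from driftquant import DropletReaction, SubsampleRecord, StomachRecord, copies_per_g

wells = [DropletReaction(f"A{i}", "2017-I-03", i, 18000 + 200*i, npos, dilution=10.0)
         for i, npos in [(1, 2512), (2, 2694), (3, 2388), (4, 2601), (5, 2455)]]
subs = [SubsampleRecord("2017-I-03", i, wet_weight=0.2) for i in range(1, 6)]
stomach = StomachRecord("2017-I-03", "I", 2017, fish_weight=455.0, content_weight=9.3)

res = copies_per_g(wells, subs, stomach)
print(f"copies/uL reaction (mean): {res.copies_per_ul_reaction:.1f}")
print(f"mt16S copies per g stomach content: {res.copies_per_g:.3e}")
print(f"replicates used: {res.n_replicates}, flags: {res.flags or 'none'}")
```

prints

```
copies/uL reaction (mean): 172.1
mt16S copies per g stomach content: 2.065e+07
replicates used: 5, flags: none
```

Reading: a ~14 % positive-droplet fraction corresponds to ~172 template
copies per µL of reaction; multiplied through the dilution and volume chain
and divided by 0.05 g of tissue per subsample this is a strong predation
signal of ~2 × 10⁷ gene copies per gram — orders of magnitude above the
detection limit, typical of a stomach containing recently ingested larvae.

The command line exposes the same stages:

```bash
driftquant make-synthetic --out inputs/ --seed 1
driftquant simulate-drift --currents inputs/currents.nc --out drift/ --seed 1
driftquant quantify-ddpcr --droplets inputs/droplets.csv \
    --subsamples inputs/subsamples.csv --stomachs inputs/stomachs.csv \
    --out copies.csv
driftquant survey-stats --copies copies.csv --out stats/
driftquant run-all --out run/ --seed 1      # everything, one command
```

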