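# Methods

This note documents the models implemented in `thawnitro`, their
assumptions, the defaults and why, what the synthetic generators emulate,
and the numerical choices made where the design was genuinely open.

## Chamber fluxes

The static-chamber model assumes a linear rise of the headspace mixing
ratio over the ≤50-minute enclosure, i.e. the flux is not yet damped by the
growing concentration gradient. The flux is

F = s · h · P/(R·T) · M · k,

with s the OLS slope (ppm min⁻¹) over all samples, h the chamber height
(volume/area, m), P/(R·T) the molar air density, M the grams of reported
element per mole (28.0134 g N mol⁻¹ for N₂O; 12.011 g C mol⁻¹ for CH₄ and
CO₂), and k the scaling to μg (N₂O) or mg (C gases) per m² and day.
Positive = emission, negative = uptake.

Choices:

* **No point-dropping.** Field practice sometimes removes visually outlying
  samples; that step is not reproducible, so all samples enter the fit and
  r²/RMSE are reported instead. QC rejects an enclosure only when
  RMSE > 3 × SD of standard gas mixtures in the relevant range; the
  boundary itself accepts (rejection requires strict exceedance). RMSE is
  √(SSE/n).
* **Chamber height is a required input** — geometry varies between
  campaigns and a wrong default is worse than none.
* **No nonlinear (saturating) chamber models and no dissolved-gas
  correction**; both are deliberate scope limits.
* **Pore-gas gradient flux.** For surfaces where chambers cannot sit
  (e.g. beneath dead standing biomass), a one-dimensional Fickian estimate
  is provided: F = D_s·ΔC/z with the Millington–Quirk effective diffusivity
  D_s = D₀·θₐ^(10/3)/φ², D₀ = 1.43×10⁻⁵ m² s⁻¹ for N₂O at 293 K scaled by
  (T/293)^1.75. This is the package's own design choice of a standard
  soil-gas transport model; it assumes steady state and a uniform profile,
  and should be read as an order-of-magnitude estimate, not a calibrated
  flux.

## Soil physics

WFPS = θ_v/φ with φ = 1 − ρ_bulk/ρ_particle. Apparent WFPS > 1 (possible
with field moisture-probe error) is reported as-is with a warning, never
silently clipped — saturation information matters for interpreting N₂O
uptake. Particle density defaults to 2.65 g cm⁻³ (mineral soil) when not
measured and is flagged as assumed in table output. Extract concentrations
convert to dry-weight basis via dry mass = fresh/(1 + gravimetric water).

## Gross and net N transformation rates

Gross rates use the isotope pool-dilution principle: label the product pool
(NH₄⁺ for mineralization, NO₃⁻ for nitrification) with ¹⁵N; production
adds unlabeled N and dilutes the enrichment, consumption removes both
isotopes proportionally. Under constant gross production p and consumption
c between two extractions,

p = (ΔM/Δt) · ln(APE₀/APE_t) / ln(M_t/M₀),  c = p − ΔM/Δt,

switching to the limit form p = (M₀/Δt)·ln(APE₀/APE_t) when
|ln(M_t/M₀)| < 10⁻⁹. This analytical estimator is exact under the
constant-rate model dM/dt = p − c, dH/dt = −c·H/M (verified in the tests
against an independent Euler integration of that ODE system).

Choices and caveats:

* The first extraction (4 h after labeling) is treated as the initial
  state (M₀, APE₀) rather than the nominal labeling time, avoiding the
  assumption of instantaneous label mixing. Both times are configurable.
* When APE_t ≥ APE₀ (no dilution — immobilization dominated) or a pool is
  non-positive, the result is flagged non-determinable with a reason code
  instead of returning a negative production. This mirrors the real
  limitation of the method in N-poor, strongly immobilizing soils.
* Net rates are simple pool differences over time; net mineralization =
  net ammonification + net nitrification holds by construction. The small
  N addition that accompanies labeling is part of the measured pools and
  needs no correction.
* No simultaneous numerical fitting of remineralization (FLUAZ-style) —
  out of scope.

## Incubation rates and denitrification partitioning

Oxic flasks: production is the OLS slope over the first four sampling
points (days 0–3 of the 0/1/2/3/6 schedule); the day-6 point may saturate.
Anoxic flasks (with or without acetylene): the maximum production rate
between two consecutive sampling points, because N₂O consumption (without
acetylene) or steady state (with) typically follows the production phase.
No smoothing; raw consecutive intervals. Negative maxima (monotone decline:
net consumption throughout) are reported with a flag, not zeroed — they are
information about N₂O reduction to N₂.

Acetylene (10 vol-%) blocks N₂O reductase, so the acetylene treatment
measures total denitrification; N₂ = max(0, total − anoxic), and the
total/anoxic ratio expresses how much of the denitrification flux escapes
as N₂. Amendment responses are plain rate ratios against the control.
Headspace amounts only — no dissolved-N₂O (Bunsen solubility) correction,
a documented limitation acceptable because treatments are compared
internally at one temperature.

## Erosion geometry and the N budget

**Retreat.** Transects are cast perpendicular to the shoreline baseline at
fixed spacing (default 10 m); per transect and dated cliff polyline the
distance from the baseline to the *nearest* intersection is taken (robust
when a sinuous cliff line is crossed more than once); the per-transect
retreat rate is the distance change divided by the elapsed years, and the
section is summarized by the median and quartiles. Transects missing either
dated line are dropped and counted. Coordinates are planar metric; no
geodesy.

**Volume.** Eroded volume sums positive elevation loss (old − new) × cell
area over valid cells, optionally within a polygon mask. Negative
differences (deposition/uplift) do not offset losses, per the convention
that positive change means thaw subsidence.

**Budget.** The chain is linear: annually eroded volume per unit area
× (1 − ice fraction) → sediment volume; × bulk density → sediment mass;
× total-N mass fraction → total N release (kg m⁻² yr⁻¹); × mineral-N
content → mineral N release (g m⁻² yr⁻¹). The normalizing area for
"volume per unit area" is the **annually eroded footprint** (median retreat
rate × section length): the areal basis of the N-release figures is then
the strip of ground actually consumed each year, which is also the basis on
which the emission factor makes sense. Defaults carry the Yedoma
characteristics (ice 82 vol-%, ρ 1220 kg m⁻³, TN 0.16%, mineral N
35.3 mg kg⁻¹).

**Emission factor.** Seasonal N₂O-N loss = median daily flux × 100-day
snow-free season; the emission factor is that loss as a percentage of the
mineral N liberated per m² of thaw front in a year, and is compared as a
fold-ratio against the IPCC 1% default for N inputs to managed mineral
soils. On the measured constants the chain gives 5.076 m³ m⁻² yr⁻¹ →
1.78 kg total, 39.35 g mineral N m⁻² yr⁻¹ → 54.8 mg N₂O-N m⁻² → 0.139%,
7.2-fold below 1%. (The printed rounded figures 1.7 kg and 39 g are not
exactly co-reproducible from one intermediate — 39/[35.3/1600] ≈ 1.77 —
so the chain here is anchored on the mineral-N figure, with total N
agreeing within rounding.)

## Gene community summaries

Relative abundances are plain count proportions of all captured
functional-gene sequences per sample (an `other` column absorbs captures
outside the listed families); amoA aggregates its bacterial and archaeal
forms, nir aggregates nirK + nirS. No length/copy-number correction of
captured reads and no compositional (log-ratio) transform — percentages
are what the downstream comparisons use. The (nirK+nirS)/nosZ ratio is
computed per sample, then summarized as mean ± SE (n = 3), because the
ratio of means is not the mean of ratios. qPCR copies per g dry soil =
copies per reaction × (elution/template volume) / g extracted.

## Statistics

Kruskal–Wallis (tie-corrected, via scipy) with Dunn's pairwise z-tests on
mean ranks with pooled tie-corrected variance, implemented here and checked
against a full label-permutation oracle on small instances. The default
multiplicity adjustment is Holm (uniformly more powerful than Bonferroni at
the same family-wise error rate); `none` and `bonferroni` are selectable
because both adjusted and unadjusted displays are common in this
literature. The all-tied degenerate case returns H = 0, p = 1 with a flag.

Compact letter displays use insert-and-absorb: start with one letter
covering all groups; for each significant pair, split every letter
containing both; absorb letters that became subsets. The two display axioms
(significant ⇒ no shared letter; non-significant ⇒ ≥1 shared letter) hold
for every output (property-tested over randomized significance patterns);
minimal letter count is not guaranteed.

Wilcoxon signed-rank drops zero differences and uses the exact null for
n ≤ 25 without ties, else the tie/continuity-corrected normal
approximation; the reported statistic is the signed-rank sum, so swapping
the arguments flips its sign. Spearman's ρ uses tie-aware ranking, with an
exact permutation p for n ≤ 9 (untied) and the t-approximation otherwise.

At the small group sizes typical of such campaigns (5 groups × n = 5) the
chi-square approximation of the Kruskal–Wallis statistic is conservative:
the simulated null rejection rate at α = 0.05 is ≈0.037 rather than 0.05.
This is a property of the canonical test (identical in R and scipy), kept
deliberately; the calibration check in the tests uses a 3-SD binomial band
around the nominal level.

## Synthetic data: what it does and does not emulate

Generators produce inputs with the statistical structure each analysis
assumes and record the generating truth:

* chamber series: linear accumulation (exact inverse of the flux
  conversion) + i.i.d. Gaussian noise on mixing ratios (models GC
  analytical error; default times 0/12.5/25/37.5/50 min; ambient N₂O
  0.33 ppm);
* pool dilution: the constant-rate ODE system solved in closed form;
* incubations: linear production, then decline (anoxic) or plateau
  (acetylene) after an onset day; schedule 0/1/2/3/6 days;
* DEM pairs: a plateau–cliff–shore profile whose foot moves inland by a
  known retreat; analytic volume = retreat × length × height; dated
  boundary polylines and a shoreline baseline included; written/read as
  ESRI ASCII grids and vertex CSVs;
* gene counts: multinomial draws around prescribed relative abundances;
* surface tables: WFPS/mineral N uniform within per-class ranges; fluxes
  drawn log-uniformly within each half-range around the class median (so
  the population median equals the class median while spanning the full
  range — field N₂O fluxes are strongly right-skewed). The packaged
  profile file carries the values printed for each surface class and marks
  every unprinted quantity as assumed.

Not emulated: spatial autocorrelation, seasonal/weather dynamics,
within-surface variance components beyond the declared ranges, microbial
growth kinetics, DEM co-registration error. Passing round-trip tests
therefore demonstrates correctness of the estimators under their stated
models — not robustness to every pathology of real field data.

Problem sizes used in the test suite and acceptance script (1,000 Monte
Carlo chamber series; 1,000 null simulations for the type-I check; a
100 × 200-cell, 2-m-resolution synthetic DEM; 2×10⁵-read gene tables) were
chosen to keep Monte Carlo error well below the tolerances being checked.

## Known limitations

* The pore-gas flux is a generic diffusion estimate, not a calibrated
  method.
* Gross nitrification in strongly immobilizing soils is flagged
  non-determinable rather than estimated — matching the method's real
  behavior, but meaning the pipeline cannot quantify gross rates there.
* The erosion budget treats the cliff as a single homogeneous body; no
  hydrological routing of the mobilized N is attempted, so the emission
  factor compares an areal loss with an areal release, not a traced flux.
* Welch ANOVA / Games–Howell (the normal-data branch) is not
  re-implemented; standard statsmodels/scipy routines cover it when data
  pass normality checks.
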