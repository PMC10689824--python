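# Methods

## The data model and derived indices

One row per sample; snake_case headers; UTF-8 CSV with "." decimals and empty
cells for missing optional values (`trehalose_c`, Gram-stain PLFA splits).
`total_organic_c` is a *fraction* of dry mass; storage pools are µg C g
soil⁻¹; PLFA pools nmol g soil⁻¹; enzyme activities µg PNP g soil⁻¹ h⁻¹.
Validation is row-indexed and enforces: non-negative concentrations,
0 < SOC < 1, bacterial + fungal PLFA ≤ total PLFA, unique sample ids, and the
fertility grouping (basalt/shale = fertile, ironstone/sandstone = infertile).

The packaged fixture `table1_site_means.csv` stores the eight published site
means *as printed*, including the per-SOC storage columns. Those columns are
means of replicate-level ratios, not ratios of the printed means, so the
package never recomputes them from the other columns (dividing the printed
means gives, e.g., 521 rather than the printed 532 µg NLFA-C g SOC⁻¹ for the
first basalt site). Derived indices:

- microbial biomass C from the fumigation C flush: flush × 2.64;
- mass→molar C:P: × 31/12 (integer atomic masses by default, configurable);
- per-SOC normalisation: storage / SOC fraction;
- fungal:bacterial PLFA ratio (both pools are molar);
- storage share of biomass: (NLFA + PHB + trehalose)/MBC, missing trehalose
  counting as zero.

## The stoichiometric C–P allocation model

A homogeneous community takes up organic C and inorganic P in proportion to
their availabilities with equal affinities, so the substrate C:P ratio equals
the uptake ratio u_c/u_p. Per unit of structural growth G the community
respires (1−e)/e (growth-coupled respiration); growth is the minimum of the
C-allowed rate e·(C supply to growth) and the P-allowed rate r_B·u_p. The
switch sits at the threshold element ratio TER = r_B/e (for the reserve
strategy the constitutive fraction shifts the effective switch to
r_B/(e·(1−f_res))). Storage strategies:

- **none** — excess assimilated C under P limitation is lost as overflow
  respiration;
- **reserve** — a fixed fraction f_res of C uptake goes to storage before
  growth allocation (a growth trade-off; storage accrues under both
  limitation states);
- **surplus** — under P limitation, excess C up to phi_max·u_c is diverted
  to storage; overflow only carries what exceeds the cap.

Carbon closes exactly at every point: u_c = G + respiration + net storage
(enforced to 1e−12 relative; an internal consistency error otherwise). Net
storage is non-negative — there is no remobilisation flux, so the surplus
curve is exactly zero left of the TER; the decline of surplus storage under
P addition reflects the shrinking excess-C influx, not consumption of the
pool. Whether the original formulation includes remobilisation, uptake
saturation, or a finite storage capacity is unknown (its full equation set
is not public); this reconstruction reproduces the qualitative gradient
behaviours that are documented, with one exception noted under
*Limitations*.

Gradient sweeps change substrate C:P by raising organic C at fixed P above
the baseline ratio and raising inorganic P at fixed C below it, on a
log-spaced grid with the baseline inserted; all fluxes are normalised by the
baseline C uptake (so the baseline u_c is 1 by construction).

Default parameters: growth efficiency e = 0.45, reserve fraction
f_res = 0.15, surplus cap phi_max = 1.0. Soil parameterisations take the
biomass C:P (mass basis) and substrate C:P from the site-mean table: basalt
r_B = 29.4, baseline 59.6 (left of its TER 65.3 → C-limited); sandstone
r_B = 78.7, baseline 636 (right of its TER 174.9 → P-limited). e = 0.45 is a
mid-range community growth efficiency chosen once so that the two baselines
fall on opposite sides of their TERs, as observed; all parameters are
overridable.

## Allocation statistics

Storage scales with biomass, so "allocation" is modelled as
log(storage) ~ log(PLFA) + focal term + (1 | site), fitted by maximum
likelihood with a single profiled variance ratio (closed-form GLS per λ,
deviance tolerance 1e−8). PHB, a prokaryote-only polymer, uses bacterial
PLFA as its covariate. Group contrasts are estimated marginal means at the
overall (unweighted) mean of the log covariate.

Inference: the focal term's likelihood ratio is reported against its
asymptotic chi-square reference *and* mapped onto its F-scale equivalent
(F = (n−p)/q·(exp(LRT/n)−1)), which is the exact classical ANCOVA F when the
site variance profiles to zero. At this design size (n = 24, 8 sites) the
chi-square reference rejects a true null ~14% of the time at α = 0.05 while
the F calibration holds ~8%, so the F-based p is the package default
(`AllocationFit.p_value`); the chi-square LRT stays available in
`term_test`. CIs for EMMs and slopes use t(n−p) quantiles for the same
reason. This replaces the Kenward–Roger/parametric-bootstrap machinery that
a full mixed-model stack would provide, which is out of scope here.

Composition: PLFA markers are converted to relative molar quantities,
transformed log_e(1 + x), compared by Bray–Curtis dissimilarity, and tested
by one-way PERMANOVA (Anderson's pseudo-F; free permutation of sample
labels, default 999 permutations, mandatory seed, p = (1 + exceedances)/(1 +
permutations), bit-reproducible per seed).

## Incubation analysis

Respiration rates measured on days 0 (pre-treatment), 1, 2, 3, 4, 8, 10 are
integrated by the trapezoid rule over the measured days; the day-0 point
anchors the curve and is included. Effects are log response ratios
rr = ln(mean_t/mean_c) with the delta-method standard error
√(s_t²/(n_t·m_t²) + s_c²/(n_c·m_c²)) and z-based 95% intervals (the interval
construction behind the published figure is unstated; the delta-method
normal interval is the conventional default and matches a nonparametric
bootstrap within a tenth of the interval width on the tested arms). An
effect is "significant" when its interval excludes zero. Covariate-adjusted
treatment contrasts use OLS of log response on log covariate plus
soil × treatment factors with a type-II ANOVA table.

## The synthetic-data generator

The generator emulates the *design and the assumed statistical structure*,
not the chemistry: 4 soil types × 2 sites × 3 replicates. Log PLFA is drawn
per soil type around geometric means calibrated to the site-mean table
(54/44/18/19.5 nmol g⁻¹); the replicate log-SD of 0.25 matches the
replicate-level CV implied by the printed standard errors (SE·√3). Log
storage follows intercept(type) + slope·(log PLFA − mean) + site effect +
noise, with slope 1.0, site SD 0.1, residual SD 0.2, exponentiated so all
values are positive. Default intercepts put NLFA and PHB allocation 2.5-fold
higher on infertile types and leave trehalose flat; fungal fractions (0.19
fertile, 0.37 infertile) yield the observed 2–3-fold fungal:bacterial
contrast. Phosphodiesterase is generated as an exogenous driver
(log-normal, SD 0.4) whose link (default slope 0.8) feeds PHB allocation,
so the continuous-predictor fit has a well-defined true slope.

The incubation generator scales a fixed rate-curve shape so control
integrals hit 454 (basalt) and 201 (sandstone) µg CO₂-C g⁻¹, applies
multiplicative treatment effects to post-treatment days and day-10 pools
(glucose: respiration and MBC ×4, fungal PLFA ×3, NLFA ×3, PHB ×2.5 in both
soils; phosphate: respiration ×2 and bacterial PLFA ×1.8 in the sandstone
soil only), and adds mean-one lognormal replicate noise (SD 0.15, n = 5 per
cell). All randomness derives from one root seed via spawned per-component
streams; identical configs are bit-identical.

What a green test does **not** establish: the generator has no spatial
autocorrelation, no measurement-method error structure, no trehalose
missingness mechanism, and lognormal noise everywhere — real data can
deviate from all of these. Power/type-I/coverage statements are claims about
this stated world only.

## Numerical and design choices

- Ties in range summaries break to the first sample in input order.
- The limitation flag at exactly the TER is "C-limited" (fluxes are
  continuous there, so the label is cosmetic).
- The profiled-deviance λ search runs on a log grid (10⁻⁸–10⁶) with bounded
  refinement and an explicit λ = 0 boundary comparison; a boundary fit
  records a "singular fit" warning but still returns estimates. Residual
  variance is floored only to keep logs finite in exactly-deterministic
  corner cases.
- Zero storage values cannot be log-fitted; the generator never emits zeros
  and real zeros would need an offset chosen by the analyst (validation
  raises rather than guessing).
- With zero within-type covariate spread the group + covariate design is
  rank deficient and group EMMs are non-identifiable; the noise-free test
  worlds therefore keep the covariate's spread.

## Limitations

- The flux model conserves C exactly, which forces respiration to *fall*
  under P addition for the no-storage and reserve strategies (former
  overflow becomes growth); the original description reports respiration as
  unaffected there, suggesting its (non-public) equations regulate uptake
  rather than overflow. All other documented gradient behaviours are
  reproduced.
- The mixed model fits one variance component (site); no crossed or nested
  extensions, no REML (ML is required for the nested fixed-effect tests).
- PERMANOVA permutes freely (no strata), matching the default of the
  standard implementation.
- Delta-method response-ratio intervals at n = 5 per arm undercover mildly
  (~91% measured against a nominal 95% on the null synthetic incubation);
  a bootstrap alternative is available through the testing oracle but not
  wired as the default, to keep the published convention.
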