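# soilstore

Tools for analysing **microbial carbon-storage allocation across soil
fertility gradients**. Soil microorganisms bank carbon in intracellular
compounds — triacylglyceride storage lipids (measured as neutral lipid fatty
acids, NLFA), the bacterial polymer polyhydroxybutyrate (PHB), and the
disaccharide trehalose — and the extent of that banking shifts along
gradients of substrate stoichiometry. This package implements the full
analysis chain for a four-parent-material gradient (basalt, shale, ironstone,
sandstone; two sites each) and a glucose/phosphate amendment incubation:

- **data model** (`soilstore.data`): a tidy per-sample schema for soil
  chemistry, PLFA/NLFA/PHB/trehalose pools and enzyme activities, with the
  published eight-site mean table packaged as a fixture, plus derived indices
  (fumigation-flush conversion with factor 2.64, per-SOC normalisation,
  mass↔molar C:P with masses 12 and 31, fungal:bacterial ratios, storage
  share of microbial biomass C).
- **stoichiometric model** (`soilstore.stoich`): steady-state C–P flux
  partitioning for a homogeneous community with growth efficiency *e* and
  biomass C:P ratio *r<sub>B</sub>*, under three storage strategies — none,
  constitutive *reserve* (fixed fraction *f<sub>res</sub>* of C uptake), and
  plastic *surplus* (excess C under P limitation goes to storage instead of
  overflow respiration). The threshold element ratio TER = *r<sub>B</sub>/e*
  separates C- from P-limited growth; gradient sweeps normalise all fluxes by
  the baseline C uptake.
- **allocation statistics** (`soilstore.allocation`): mixed models of
  log storage on log PLFA-C (bacterial PLFA-C for PHB) with soil type or a
  continuous predictor as the focal term and a random site intercept;
  estimated marginal means at the overall mean covariate; likelihood-ratio
  tests (with an F-scale small-sample calibration); Bray–Curtis
  dissimilarities and PERMANOVA for PLFA composition.
- **incubation analysis** (`soilstore.incubation`): trapezoid-integrated
  cumulative respiration and log response ratios
  ln(X̄<sub>treatment</sub>/X̄<sub>control</sub>) with delta-method 95%
  intervals, plus covariate-adjusted factorial ANOVA.
- **synthetic data** (`soilstore.synth`): seeded generators reproducing the
  gradient (4 types × 2 sites × 3 replicates) and incubation
  (2 soils × 3 treatments × 5 jars) designs, with a recovery harness for
  power, type-I error and CI coverage.

## Worked example

```python
from soilstore import data, stoich

ds = data.load_table1_fixture()
nlfa_max, site = data.summarise_range(ds, "nlfa_c", "max")
fold = data.fungal_bacterial_contrast(ds)
print(nlfa_max, site, round(fold, 2))
```

prints `22.3 basalt_site_1 2.41`: storage-lipid C peaks at 22.3 µg C per g
soil on the most fertile site, and fungal:bacterial PLFA ratios average
2.41-fold higher on the infertile (ironstone/sandstone) soils — fungi, which
bank C constitutively, dominate where P is scarce.

```python
params = stoich.SANDSTONE_PARAMS          # biomass C:P 78.7, baseline C:P 636
print(round(stoich.threshold_element_ratio(params), 1))
sweep = stoich.sweep_gradient("all", params, 20, 20000, 201)
```

prints `174.9`: the sandstone community sits far right of its threshold
element ratio, so it is P-limited at baseline; in the sweep, added C raises
respiration one-for-one without storage, by 0.85 per unit C with reserve
storage, and not at all with surplus storage (the excess is banked instead).

The numbered scripts under `analysis/` run the same stages end to end and
write their tables to `results/`:

```
python analysis/01_fixture_summaries.py    # ranges, per-SOC means, F:B contrast
python analysis/02_model_sweeps.py         # both soils x three storage modes
python analysis/03_allocation_models.py    # mixed fits + PERMANOVA (synthetic)
python analysis/04_incubation_effects.py   # log response ratios
python analysis/05_recovery_experiments.py # power / type-I / coverage table
```

There is also a CLI: `soilstore reproduce-paper`, `soilstore simulate-model`,
`soilstore generate-synthetic`, `soilstore analyze-gradient`,
`soilstore analyze-incubation` (every seeded command requires `--seed` and is
byte-reproducible).

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from the packaged site-mean table and the full pipeline, the
headline gradient quantities (storage-pool range endpoints, the total-N
maximum, the mean per-SOC NLFA content, and the infertile:fertile
fungal:bacterial fold difference) and writes them as JSON keyed t1–t6. It
also re-runs both stoichiometric sweeps and aborts if C mass balance is
violated anywhere.

See `docs/methods.md` for model assumptions, parameter defaults, statistical
calibration choices and known limitations.
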