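# cementochron

Life-history inference from annual increments in dental cementum
(**cementochronology**), for paleobiologists and zoologists working
with tomographic or histological tooth-root images.

Dental cementum grows throughout life and is almost never remodeled:
each year adds one growth layer group (GLG) — a thick light
(favorable-season) increment and a thin dark one.  Counting light
increments along radial grayscale transects gives an individual's age
at death; the widths of successive GLGs track its somatic growth rate;
and the texture of the tissue changes when growth truncates at sexual
maturity.  `cementochron` implements the full chain:

* **synthgen** — synthetic cementum images with annual banding, a
  hyaline layer, an outer phase fringe, cellular voids, noise, and a
  juvenile→adult texture shift, plus exact ground truth; Brownian-motion
  trait simulation on phylogenies.
* **imgstack** — virtual thin sections (10-slice z-projection), ROI
  straightening, boundary-artifact trimming, cellular-void screening.
* **increments** — the five-segment mean+SD peak rule: a light
  increment is a run of transect samples exceeding its segment's
  mean + 1 SD; widths are peak-to-peak distances (final year excluded);
  life span is the modal count across 8 transects × 9 sections.
* **allometry** — the printed log₁₀ regressions:
  `log10 w1(μm) = 0.270·exp(0.340·log10 M(g)) + 0.564` (first-year
  width from mass, used to normalize widths into mass-specific growth
  rates, msGR), `log10 msSMR = −0.237·log10 L − 0.083` (mammal) /
  `−0.83·log10 L − 0.31` (reptile), and
  `dentary(mm) = 10.184·lm1 + 8.026`.
* **growthfit** — ten growth-curve families fitted by multi-start
  least squares, ranked by `AIC = n·ln(RSS/n) + 2k` with r² breaking
  ΔAIC < 2 ties; growth-rate truncation windows and maturity ranges.
* **texture** — 21 areal surface-texture measures (grayscale as
  height), ANOVA screening, PCA, and convex-hull overlap of
  juvenile vs adult texture space.
* **phylocomp** — Brownian-motion PGLS, nonlinear phylogenetic
  regression (BM/OU errors, ML + rejection ABC), phylogenetic ANCOVA,
  pooled ANOVA with Cohen's d.
* **pipeline** — YAML-configured end-to-end runs with a serialized
  manifest.

See `docs/methods.md` for the model and all numerical choices, and
`docs/texture_measures.md` for the texture formulas.

## Worked example

```sh
cementochron run examples/demo_config.yaml
```

simulates two ten-specimen cohorts — a crown-mammal-like taxon
(130 g, sigmoidal growth schedule, texture shift at maturity year 5)
and a stem-mammaliaform-like taxon (20 g, shallow quadratic decline,
no shift) — then measures every specimen blind to the ground truth.
From an actual run (seed 1):

`model_selection.csv`

```
taxon,family,aic,r2,delta_aic_runner_up,params
crown_mammal_like,hill_sigmoid,-28.52,0.996,20.16,"[6.997585, 2.491949, 4.94669, 6.684404]"
mammaliaform_like,quadratic,-37.40,0.999,5.50,"[8.077133, -1.385185, 0.091469]"
```

`maturity.csv`

```
taxon,truncation_min_age,truncation_max_age,maturity_min_age,maturity_max_age
crown_mammal_like,4,5,3.0,6.0
mammaliaform_like,1,2,0.0,3.0
```

`hull_report.json`

```
{"crown_mammal_like": {"overlap": 0.0, "distinct": true}}
```

Reading: AIC selection recovers each cohort's generating growth family
(a decreasing Hill sigmoid vs a quadratic; ΔAIC to the runner-up 20.2
and 5.5); the steepest year-to-year msGR decline for the crown-like
taxon falls at years 4–5, bracketing the true maturity year 5; and its
juvenile and adult cementum occupy disjoint convex hulls in PC1–PC2
texture space (overlap 0), while the shift-free mammaliaform cohort
never yields enough long-lived specimens past the 5-year cutoff to
claim a contrast.  Per-specimen life-span counts are written to
`lifespans.csv` together with the msSMR each implies.

Single quantities, from Python or the CLI:

```text
$ cementochron bmr --lifespan 14 --clade mammal
msSMR = 0.4419 ml O2 / (h g)  [mammal, life span 14 y]
$ cementochron mass --lm1-mm 1.5
dentary length = 23.302 mm
```

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the full pipeline from scratch under the given seed (synthetic
cohort generation → increment detection → life spans → msGR pooling →
growth-model selection → truncation/maturity → texture discrimination)
and writes the results-manifest JSON to `--out`; the run's tables land
in `scratch/acceptance_run/`.
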