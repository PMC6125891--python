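# rangerecon

Reconstructing multi-decade **range change** of a terrestrial mammal from
period-binned occurrence records, and prioritizing what is left of the
range for conservation. The pipeline was built around the textbook case
of the Chinese pangolin (*Manis pentadactyla*) in eastern China, whose
potential distribution contracted by roughly half between the 1970s and
the early 2000s under intensifying human pressure, retreating upslope
into mountain refugia.

It is aimed at conservation ecologists who have (i) occurrence points
binned into time periods (gazetteer, survey or interview records),
(ii) per-period environmental raster stacks, and (iii) road/reserve
vector data — or who want to study the behaviour of this class of
analysis on synthetic landscapes with a known ground truth, which the
package generates itself.

## What it computes

For periods *t* = 1…P with occurrences *O_t* and environmental stacks
*E_t*:

- **Ensemble SDM per period.** Several classifier techniques × R
  evaluation runs on stratified 80/20 splits, each scored by the true
  skill statistic TSS = sensitivity + specificity − 1 over a 0.01
  threshold grid. Fits with TSS ≥ the fit-set mean become ensemble
  members; the member-mean probability is binarized at the cut-off *P*
  maximising ensemble TSS (present ⇔ p > *P*); K whole-pipeline
  repetitions are combined by cell-wise majority. Occurrences are thinned
  to one record per home range (6.97 ha default), pseudo-absences drawn
  from a 15-km road buffer, predictors screened at VIF < 10.
- **Range accounting.** range_km² = presence cells × cell area; percent
  reductions 100·(1 − r_b/r_a) between and against periods, mean decadal
  rate, share of study area, mean elevation of the occupied range.
- **Niche change (PCA-env).** Kernel-smoothed, availability-corrected
  occupancy surfaces in the space of the first two principal components
  of the standardised environment; Schoener's
  D = 1 − ½Σ|z₁ − z₂| between each period's partial niche and the total
  niche, tested against B random same-size subsamples of the pooled
  occurrences.
- **Core-area zonation.** Iterative removal of the cell with the smallest
  δᵢ = maxⱼ wⱼ qᵢⱼ / cᵢ (feature fraction over remaining cells, divided
  by cost), giving a rank surface in (0, 1]; condition layers degrade the
  feature (p′ = p·(1 − urban)·forest·veg) and the cost encodes how long
  ago each cell lost the species. Ranks reclassify into Mandatory
  (> 0.95) / Negotiated / Partial / Other zones and summarise over
  reserve or prefecture polygons.
- **Climate-vs-human counterfactual.** A model trained on an early
  period projected onto recent climate + early human layers; if that
  hybrid range is not smaller than the actual recent range, the observed
  contraction is not attributable to climate.

See `docs/methods.md` for assumptions, parameter defaults and numerical
choices.

## Worked example

A 50×50 km synthetic scenario with a known human-driven contraction
(`seed=11`, occurrence counts 150/110/70/40):

```python
from rangerecon import ScenarioConfig, RunSettings, run_scenario
from rangerecon.types import GridSpec

cfg = ScenarioConfig(grid=GridSpec(50, 50), seed=11,
                     occurrences_per_period=(150, 110, 70, 40))
res = run_scenario(cfg, RunSettings.fast())
print(res.table.to_frame().to_string(index=False))
```

```
period  range_km2  percent_of_study_area  reduction_vs_baseline_pct  inter_period_reduction_pct
 1970s      323.0                  12.92                       0.00                        0.00
 1980s      344.0                  13.76                      -6.50                       -6.50
 1990s      203.0                   8.12                      37.15                       40.99
 2000s      138.0                   5.52                      57.28                       32.02
```

The estimated range holds steady through the 1980s, then collapses: a
57 % loss by the 2000s (negative values are expansions; at this small
scenario size the first step is within estimation noise). The occupied
range also climbs from 641 m to 870 m mean elevation — the upslope
retreat that low-elevation human pressure forces. Consensus TSS per
period is 0.71/0.77/0.86/0.90 (skill rises as the range concentrates),
and the partial-vs-total niche overlap falls from D = 0.61 (1970s,
p = 0.29) to D = 0.37 (2000s): the recent realized niche is a shrinking,
non-random corner of the species' total niche. The zonation stage ranks
all 2 500 cells and puts exactly 125 (5 %) in the Mandatory Reserve zone.

The same accounting applied to published per-period range sizes:

```bash
rangerecon table --ranges 155929,104093,92271,74537
```

```
period  range_km2  percent_of_study_area  reduction_vs_baseline_pct  inter_period_reduction_pct
    P0   155929.0                  30.41                       0.00                        0.00
    P1   104093.0                  20.30                      33.24                       33.24
    P2    92271.0                  18.00                      40.82                       11.36
    P3    74537.0                  14.54                      52.20                       19.22
mean decadal reduction: 21.27%
```

i.e. a 52.20 % overall contraction at an average 21.27 % per decade, with
the 1970s range covering 30.41 % of the 512 684 km² study area.

## CLI

```bash
rangerecon simulate --config scenario.yaml --out data/   # synthetic bundle
rangerecon run-all  --config scenario.yaml --out out/    # full pipeline
rangerecon table    --ranges 155929,104093,92271,74537   # range accounting
```
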