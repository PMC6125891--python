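# Methods

`rangerecon` reconstructs multi-decade range change for a terrestrial
mammal from period-binned occurrence records and environmental rasters,
and prioritizes the remaining range for conservation. Because the
motivating use case (the Chinese pangolin in eastern China, 1970s–2000s)
has no public data bundle, the package ships a synthetic-landscape
generator with a known ground-truth contraction; every stage of the
pipeline is validated by recovering that truth.

## Pipeline model

For each decadal period *t* with occurrence set *O_t* and environmental
stack *E_t* (eight variables: MAT, MAP, NFFD, Eref, elevation, aspect,
forest fraction, urban fraction on a common 1-km grid):

1. **Thinning.** Records are greedily deduplicated in input order at
   minimum distance `d_min = max(2·√(A/π), cell)` where *A* is the
   home-range area (default 6.97 ha → 297.9 m diameter, floored at the
   1-km cell). The diameter is the natural non-overlap criterion for two
   circular home ranges; the floor matches the analysis resolution. Greedy
   order makes thinning deterministic and maximal (no removed point can be
   restored without violating `d_min`); it is not a maximum-independent-set
   solver.
2. **Pseudo-absences.** Historical records follow the transport network,
   so 10 000 background points (desk-scale studies use 2 000) are drawn
   uniformly from cells within 15 km of roads, excluding presence cells.
   Restricting absences to the same accessibility zone as the presences
   keeps the two samples' observation bias comparable. One draw per
   period, seeded per period.
3. **Collinearity screening.** Stepwise elimination on the variance
   inflation factor, threshold 10: while any VIF ≥ 10 the worst predictor
   is dropped and VIFs recomputed; exact collinearity yields VIF = ∞ and
   goes first; ties drop the later column. The schedule is stepwise-max —
   the standard practice where only the tool and threshold are conventions.
4. **Ensemble SDM.** Each registered technique (default: regularized
   logistic, random forest, gradient-boosted trees, spline logistic; a
   shallow neural net is registered but opt-in) is fitted on R = 10
   stratified 80/20 presence/background splits and scored by the true
   skill statistic, TSS = sensitivity + specificity − 1, maximised over
   the threshold grid 0.00, 0.01, …, 1.00 (ties → lowest threshold).
   Fits with TSS ≥ the mean TSS of all fits become ensemble members
   (≈ the better half); the ensemble probability is their unweighted mean
   (TSS-weighted optional). The presence cut-off *P* is the
   TSS-maximising threshold of the ensemble on the pooled held-out data,
   and "present" means strictly > *P*. The whole procedure repeats
   K = 10 times; a cell is in the final range if present in ≥ 50 % of
   repetitions, and the consensus probability is the repetition mean.
   Classes are balanced by equal-total weights (the presence:background
   imbalance is up to 117:10 000). Per-period models are fitted
   independently; no temporal pooling.
5. **Range accounting.** Range = presence cells × cell area; mean
   elevation is averaged over presence cells (undefined for an empty
   range). Percent reductions are recomputed from stored ranges at render
   time, rounded to two decimals for display only. The "mean decadal
   reduction" is the arithmetic mean of consecutive inter-period
   percentage reductions — a simple mean over differing baselines, not a
   compound rate, matching how such declines are customarily reported.
   Note: with the published range sizes (155 929, 104 093, 92 271,
   74 537 km²) the 1990s-vs-1970s reduction computes to 40.82 %, not the
   40.32 % usually quoted alongside them; the package always reports the
   computed value.
6. **Niche overlap (PCA-env).** All variables are standardised over the
   pooled valid cells of all periods and projected on the first two
   principal axes (sign convention: largest-|loading| positive per axis).
   Occurrence and availability densities are estimated on an R = 100
   lattice spanning the pooled availability, by exact Gaussian product
   kernels with per-axis normal-reference bandwidths. Occupancy
   z = (z_occ / z_env) renormalised, zero where nothing is available.
   Niches are compared by Schoener's D = 1 − ½Σ|z₁ − z₂|. Each period's
   partial niche is tested against the total niche by drawing B = 100
   same-size random subsamples of the pooled occurrences;
   p = (1 + #{D_null ≤ D_obs}) / (B + 1) (add-one avoids p = 0),
   one-tailed for "less similar than sampling noise explains". All eight
   variables enter the PCA by default (configurable subset).
7. **Prioritization (core-area zonation).** The feature layer is the most
   recent period's consensus probability, degraded by condition layers
   p′ = p·(1 − urban)·forest(·vegetation) — urban is inverted because it
   is a pressure. The cost layer encodes disappearance time: d = trailing
   absent periods / (P − 1) ∈ {0, ⅓, ⅔, 1} for four periods (0 = still
   present in the last period, 1 = absent throughout), with c = 1 + d —
   bounded, strictly positive, monotone in absence duration (c = 0.05 + d
   available for a stronger effect; d's polarity is configurable because
   the verbal convention is genuinely ambiguous). Cells are removed
   iteratively, always the one minimising
   δᵢ = maxⱼ wⱼ·p′ᵢⱼ/Σ_remaining p′ⱼ / cᵢ, with exact denominator updates
   after every removal (no warp/edge-removal speed-ups; at ≤ 10⁴ cells the
   exact algorithm takes seconds). Ties break by lower conditioned value,
   then row-major index. The rank of the cell removed at position i of N
   is i/N. Zones: Mandatory > 0.95, Negotiated (0.90, 0.95], Partial
   (0.80, 0.90], Other ≤ 0.80 — half-open intervals close the 0.89–0.90
   gap the verbal rule leaves; rank 0.90 is Partial. Polygon summaries use
   mean rank with level thresholds 0.90/0.80 (priority/important/normal,
   configurable — the official reserve rule is not public).
8. **Counterfactual.** To ask whether climate alone explains the decline,
   a model trained on an early period (its occurrences and human layers)
   is projected onto a hybrid stack: recent climate + early human layers.
   If the projected range is not smaller than the actual recent range,
   climate is a neutral-or-positive factor and the contraction is
   attributable to human pressure.

## Synthetic scenarios

The generator emulates the statistical structure the analysis assumes,
not any real geography:

- **Terrain** — a sum of 3–6 low-frequency sinusoids plus seeded Gaussian
  noise, rescaled to 0–1500 m; fixed across periods. Simple,
  dependency-light and exactly reproducible; it lacks the anisotropy and
  drainage structure of real terrain.
- **Climate** — MAT = 21 °C − 6.5 °C/km lapse + smooth noise (sd
  1.5 °C); MAP, NFFD, Eref are smooth fields moderately correlated with
  elevation. The noise scales are set so predictors are correlated but
  all VIFs sit below 10 on the physical layers (realistic mild
  collinearity) — except where urbanisation makes forest ≈ 1 − urban in
  late periods, which occasionally triggers a VIF exclusion, mirroring
  how real studies lose one variable in one period. Climate is
  period-constant, which is what makes the counterfactual climate-swap a
  clean neutrality control.
- **Roads and urban growth** — roads are polylines through low-elevation
  way-points (valley corridors); urban cover is a saturated field
  concentrated near roads (8-cell decay) and low elevations (500-m
  decay), scaled by per-period growth factors 0.25/0.45/0.70/1.00, hence
  cell-wise monotone. Forest is its clamped complement minus a fixed
  disturbance field. Aspect is circular uniform noise — a deliberate
  nuisance predictor.
- **True niche** — s = Gauss(elev; 600 m, 350 m) · Gauss(MAT; 17 °C,
  4 °C) · exp(−β_t·urban) with β = (1, 2.5, 4.5, 7) ×
  `contraction_strength`. Rising β plus growing urban makes the
  suitable area shrink and retreat upslope *emergently*: over 20 seeds
  the expected count of cells with s > 0.5 falls every period and the
  mean elevation of sampled occurrences rises every period.
- **Occurrences** — cells drawn without replacement with probability ∝ s
  (one record per cell, matching post-thinning structure); default counts
  714/561/322/117 per period. Default grid 100×100 at 1 km (10⁴ km²):
  large enough for ensemble fitting, small enough for exact zonation.

What passing the synthetic tests does **not** show: performance under
georeferencing error, spatially autocorrelated observation effort beyond
the road bias, climate change over time, or real land-cover texture. The
generator's monotone urban growth is an assumption; real land-cover
vintages differ in more ways than intensity.

## Problem sizes of the shipped studies

The recovery study (and `SDMSettings.fast`) runs 10 seeds of the default
100×100 scenario with a single smoothed random forest (80 trees, leaf
size 5), R = 5 evaluation runs, K = 3 repetitions and 2 000
pseudo-absences — chosen because the forest captures the unimodal
elevation/temperature response that linear members cannot, giving
low-variance range estimates at desk scale. The full-size defaults
(4 techniques, R = K = 10, 10 000 pseudo-absences) remain available via
`RunSettings()`. The null calibration uses 200 replicates at B = 100
subsamples on an R = 60 lattice; the zonation oracle uses 8×8 grids where
brute-force step simulation is exact.

## Numerical choices

- TSS threshold grid is fixed at step 0.01 (101 points); ties resolve to
  the lowest threshold, and the TSS = 2/3 worked example resolves to
  threshold 0.30 accordingly.
- Kernel densities are evaluated exactly (no binning); surfaces are
  normalised to sum 1 and Schoener's D rejects inputs off by > 1e-6.
- Occupancy floors availability at machine epsilon; occurrence mass in
  unavailable cells is zeroed (warned above 1 % of mass).
- All randomness flows through `numpy` SeedSequences keyed by
  (seed, stream); every generator output is a pure function of its
  config, and reruns are bit-identical.
- Degenerate inputs fail loudly: empty road networks, single-class
  training data, constant predictors, unnormalised niche surfaces and
  zero-baseline reductions all raise with named causes. An all-zero
  feature layer after conditioning degrades to ranking by cost with a
  warning.

## Known limitations

- The technique registry reimplements the *ensemble logic* around
  standard scikit-learn classifiers; it does not numerically replicate
  any particular legacy SDM platform's per-technique output.
- Pseudo-absence sampling is cell-based; sub-cell placement is not
  modelled.
- The zonation implementation is the exact core-area rule only — no
  boundary-length penalty, connectivity term, or removal warp — and is
  intended for grids up to ~10⁵ cells.
- Polygon summaries count cells by centre-in-polygon; slivers narrower
  than a cell can be missed.
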