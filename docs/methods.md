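# Methods

## The measurement model

All quantitative statistics operate on the peak-area ratio
PAR = analyte peak area / internal-standard peak area of the same
injection, which removes injection-level variability (injection volume,
ionization efficiency common to co-eluting species) but not batch- or
order-dependent systematic error. The package models an observed PAR as

```
PAR_obs(i, s) = PAR_true(i, s) · B(batch(i), s) · D(i, s) · ε(i, s)
```

with `B` a per-batch, per-species multiplicative offset, `D` a smooth
within-batch drift in injection order, and `ε` multiplicative lognormal
noise. Multiplicative lognormal noise keeps areas positive and makes the
error heteroscedastic in raw scale but homoscedastic in log scale, which
is why the calibration analysis treats the *unweighted* log–log (power)
fit and the through-zero fit as the natural candidates, and why all
SERRF modelling happens on log intensities.

## MRM transitions

A diacyl-PI with total acyl carbons C and double bonds D has elemental
formula C(9+C) H(15+2C−2D) O13 P (glycerol + inositol + phosphate + two
fatty acids, minus four condensation waters). The precursor is the
[M−H]⁻ ion (neutral monoisotopic mass minus a proton); the product is
the fatty-acyl carboxylate anion CnH(2n−2d−1)O2⁻ (atoms plus one
electron). Masses come from a single constants table of IUPAC/CODATA
monoisotopic values and are reported to 4 decimals. Sanity anchors:
PI(16:0|18:1) → 835.5342 / 281.2486 (18:1 product).

The 31-member endogenous default panel is a documented synthetic
stand-in: the actual monitored species list of the assay this package
models is not public, so the panel was assembled once from plausible
abundant plasma diacyl-PI species (all within total chain length 30–40
and unsaturation ≤ 6) and always includes PI(16:0|16:0), PI(16:0|18:1)
and PI(18:0|18:2), which examples and tests refer to by name. Panel
identity does not affect any downstream algorithm. Ether lipids, lyso-PI
and isomer resolution are out of scope.

## The synthetic acquisition

`SimulationConfig` defaults define the study conditions; they were chosen
once, from the structure the analysis assumes, and are not tuned:

| parameter | default | meaning / rationale |
|---|---|---|
| abundance profile | log-spaced 3.0 → 0.003 PAR | ~31 species over 3 decades |
| `noise_cv` | 0.10 | injection-to-injection CV of strong signals |
| `low_signal_noise` | 0.5 | weakest species gets 1.5 × `noise_cv`; reproduces the poorer fold-change recovery of low-abundance analytes |
| `batch_effect_sd` | 0.3 | log-space SD of per-batch, per-species offsets (no magnitudes are published for this design; this is a stand-in) |
| `drift_amplitude` | 0.15 | peak-to-peak within-batch drift, half-cosine with random phase |
| `drift_level_gamma` | 0.6 | level dependence of drift (below) |
| `interindividual_sd` | 0.8 | lognormal per-individual scale shared across species; gives >10-fold max/min total PI across ~49 donors with high probability |
| `species_jitter_sd` | 0.15 | per-individual composition jitter, so composition is far more stable than raw abundance |
| `qc_fold` | 8 | HQC = undiluted pool, LQC = the same pool 8×-diluted |
| `sample_dilution` | 8 | study samples measured at the LQC dilution, so samples sit near the LQC level |
| `cohort_effect` | 0.6 | PI level of the second study's own subjects relative to the first (a disease-cohort effect) |

The injection sequence of each batch is: system suitability, an LQC/HQC
pair, sample blocks of 15 each followed by a pair, a closing pair after
any partial block (never doubled), and a final system-suitability
injection. QC pairs are adjacent injections (L then H) so they sample the
drift curve where they sit.

**Level-dependent drift.** The drift curve is applied as
`D^(1 + γ·log10(level))` where `level` is the material's concentration
relative to the undiluted pool (HQC = 1, LQC and samples ≈ 1/8). This
models the mild signal-level dependence of matrix and detector response:
material measured far from a QC's level experiences a slightly different
systematic error than that QC reports. It is the mechanism by which the
simulation reproduces the empirically observed anchor ordering — a
QC level far from the samples corrects them worse — and it is off
(`γ=0`) in every exactness test. Magnitude 0.6 was fixed from a
back-of-envelope variance budget (anchor-mismatch scatter for the distant
QC of a few percent, comparable to but distinct from forest prediction
noise) before the ordering test was first run.

What the generator does **not** emulate: chromatographic peak shape,
carry-over, missing values, censoring at the detection limit,
isomer interference, and any real covariance structure between species
beyond the shared per-individual scale. Passing tests therefore
demonstrate correctness of the algorithms under the stated error model,
not performance on any particular instrument's data.

## Calibration

Three fits, all unweighted (the assay compares longitudinal fold changes
without an external curve, so weighting would misrepresent its use):
ordinary least squares, through-zero (`b = Σxy/Σx²`), and OLS in log–log
space. R² is computed in each model's fitted space; the through-zero R²
uses the uncentered total sum of squares, the standard convention for
no-intercept models. Back-calculated recovery is computed per replicate
and averaged per level; the linear range is the longest contiguous run of
levels whose mean recovery is within the tolerance (default ±30%), ties
broken toward the wider concentration span. On lognormally-noised data
the free intercept of the plain linear fit is resolved by the top of the
range and corrupts low-end recovery — the property suite checks that the
through-zero and power fits do not share this failure.

## Dilution linearity

Fold changes are computed within the same replicate index (each replicate
is an independently prepared series); each unordered level pair appears
once, oriented so the nominal fold is > 1 (recovery is
reciprocal-consistent, so orientation is a convention). Quantiles use
linear interpolation between order statistics (the numpy default); the
95% CI of mean recovery uses the t distribution. An alternative — fold
changes across replicate means — would shrink the spread by ~√n_reps and
is deliberately not the default, since the per-replicate statistic is
what a single acquisition delivers. Species are flagged non-responsive
when regression R² falls below a threshold; the library default (0.98)
suits low-noise acquisitions, while the pipeline uses 0.85 because at the
generator's 10–15% CV a perfectly linear response yields R² ≈ 0.90–0.96
over an 8-fold span.

## SERRF

For each target species:

1. **Anchor series.** LQC or HQC rows, or the MAAQC pseudo-series (below).
2. **Predictor selection.** The 10 companion species most
   |Pearson|-correlated with the target across anchor observations, on
   log intensities centered within batch.
3. **Features.** Companion log intensities centered within
   (batch × role group) — QC roles and samples are centered separately so
   level differences never leak into the features, while the anchor
   *target* keeps its batch offset for the forest to learn — plus
   injection order scaled to [0, 1] per batch.
4. **Forest.** 500 trees per species. With ≥ 5 anchors per batch, one
   forest per batch; otherwise one pooled forest with batch indicator
   features. The pooled forest disables bootstrap resampling (tree
   diversity comes from per-split feature subsampling): with ~3 anchors
   per batch, bootstrapping lets individual trees miss a batch entirely,
   which biases that batch's correction — with bootstrap off, a pure
   batch offset is removed exactly.
5. **Normalization.** `normalized = raw / exp(prediction) · location`,
   where `location` is the species' median anchor value over all batches.
   Anchoring the scale to the shared QC lot is what makes two jointly
   normalized studies directly comparable. Predictions are floored at
   10⁻⁶ × the species' median raw PAR (counted and logged) to preserve
   positivity.

All randomness flows from one seed through `numpy.random.SeedSequence`;
normalization is bit-reproducible at a fixed seed and library version.

**MAAQC.** The published description of the mean-adjusted average QC is
not operational, so this package defines it (flagged as an
interpretation): scale the LQC series by its own mean and the HQC series
by its own mean — both become mean-one drift profiles — average the two
position-wise, and rescale by the geometric mean of the two means, giving
one pseudo-QC observation per pair position at an intermediate level. An
alternative reading (adjusting both series to their common grand mean
before averaging) is available via `maaqc_construction="grand_mean"`;
both yield identical series means and differ only in how discordant
drift is weighted. MAAQC pseudo-observations use the average of the
paired L/H feature vectors and the pair-midpoint injection index.

Why MAAQC tends to win the anchor comparison: averaging two QC series
halves the anchor noise the forest trains on, while its effective level
sits between LQC and HQC so its level-mismatch penalty stays moderate;
LQC beats HQC whenever samples sit nearer the LQC level (here they are
measured at the same 8× dilution).

**Comparators.** `batch_median` divides each batch by its per-species QC
level (geometric mean of the LQC and HQC medians — geometric, because
the two role levels differ 8-fold) and rescales to the global geometric
mean over batches; it is exact for pure batch offsets. `qc_loess`
LOWESS-smooths role-adjusted QC log intensities against injection order
per batch, divides the drift curve out, then applies `batch_median`;
batches with < 4 QCs fall back to `batch_median` with a warning.

## Evaluation layer

* **QC acceptance**: a pair passes for a species when
  (HQC/LQC)/expected_fold ∈ [0.70, 1.30], inclusive at both ends
  (inclusivity is this package's convention; the published window is
  stated without boundary handling).
* **PCA diagnostic**: PCA of log, per-species z-scored PAR; the
  batch-separation score is the between-batch share of the total sum of
  squares of the PC1–PC2 scores (∈ [0, 1]; 0 by convention for a single
  batch). Preprocessing for this diagnostic is not published; log +
  unit-variance scaling is the standard metabolomics choice.
* **Bridging**: %Difference = 100·(a−b)/((a+b)/2) per species per shared
  sample (per-sample medians if a sample was injected more than once);
  species acceptance defaults to frac_within ≥ 0.67 at ±35% (inclusive).
  The acceptance *direction* is configurable (`accept_direction`)
  because the published wording of the species-level rule is ambiguous;
  the default accepts concordant species.
* **Anchor comparison**: per sample and species, the %difference of each
  anchor's normalized value from the across-anchor mean, then the
  per-species variance over samples. Each anchor's result is first
  rescaled per species to a common median over the compared samples —
  a per-species constant that cannot change relative scatter — because
  each anchor strategy otherwise leaves the data on its own QC level's
  scale, which would make the across-anchor average meaningless.
* **%RSE** = 100·(SD/√n)/mean over QC injections, per study, role and
  species (the term is used in this field without a printed definition;
  this is the standard one).
* **Cohort comparison**: Welch's unequal-variance t-test, two-sided, with
  Welch–Satterthwaite degrees of freedom, on raw PAR (matching the
  published choice of a "heteroscedastic t-test"; no multiple-testing
  correction, matching the reporting of raw p-values). Note that with the
  generator's 0.8 log-space inter-individual SD and a dozen subjects per
  arm, a 0.6× cohort effect is usually *not* significant at p < 0.0005 —
  the published significance claims come from larger cohorts and are not
  reproduction targets.

## Numerical choices and degenerate inputs

* Flat responses in the dilution regression: R² is defined as 0 when the
  total sum of squares is ≤ 10⁻²⁰ × Σy² (rounding residue of a constant
  series would otherwise produce an arbitrary ratio).
* Fold-change recoveries with a zero denominator are recorded as missing,
  never dropped silently; summaries report the missing count.
* %Difference with both arguments zero is missing; with one zero it is
  ±200 by continuity of the formula.
* Constant species are excluded from the PCA rotation.
* Zero variance in both groups of a Welch test yields t = 0 and a missing
  p-value.

## Problem sizes

Defaults throughout target desk-scale runs: 60 samples per study, 2
batches per study, 31 species, 3 QC pairs per batch, 500 trees per
species for production normalization (property tests use 50–200 trees,
which is ample for the structures they probe). The full pipeline runs in
well under a minute on one CPU; the acceptance script in ~10 s.

## Known limitations

* The random-forest correction is a step function of its features; with
  only 3 anchors per batch the drift estimate is coarse, which is visible
  as residual QC RSD of a few percent under drift + noise.
* MAAQC is this package's operational definition; other readings exist.
* The bridging statistic assumes shared samples were measured once (or
  summarized by median) per study; longitudinal designs need the
  `longitudinal_summary` path instead.
* The generator's batch-effect magnitudes are stand-ins; no public values
  exist for this assay family.
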