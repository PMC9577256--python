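# Methods

`nirtransfer` predicts a scalar wood property — air-dry density, g/cm³ —
from visible/near-infrared (350–2500 nm) absorbance spectra, and keeps a
model calibrated on one measurement condition usable under another. The
motivating setting is moisture content: the same specimens measured at
10 % moisture (the *source* domain) and at 30/50/70 % (the *target*
domains) give systematically different spectra — baseline offset, small
band shifts, band broadening, and swollen water O–H bands — while the
overall spectral shape is preserved. A model trained at 10 % therefore
degrades on wetter wood, and the package implements, end to end, one
particular repair strategy plus the classical alternatives it is usually
compared with.

## The pipeline

1. **Preprocessing.** 21-point Savitzky–Golay smoothing (polynomial
   order 2, polynomial-fit edge handling so shapes are preserved and any
   degree-≤2 row is a fixed point) followed by the standard normal
   variate: each spectrum centred by its mean and divided by its sample
   (n−1) standard deviation. SNV removes multiplicative scatter and
   additive offsets per spectrum, which already absorbs a pure baseline
   shift between moisture levels; what survives is the shape change.
   A synchronous 2-D correlation map (Pearson correlation between
   wavelength pairs across samples) is available as a diagnostic.

2. **Outlier screening.** A PLS regression (default 10 latent variables)
   of density on the preprocessed spectra; a sample is flagged when its
   leverage in the latent-score space (with intercept) exceeds
   3(k+1)/n or its externally studentized residual exceeds the
   two-sided t critical value at α (default 0.05). The union of flags
   over all moisture groups is removed from every group, keeping the
   groups aligned specimen-for-specimen. Both thresholds and α are
   configurable; "OR" combination is used because the two criteria
   detect disjoint pathologies (spectral vs label).

3. **SPXY splitting.** Calibration sets are chosen by the max–min rule
   on the joint distance d = d_x/max d_x + d_y/max d_y (Euclidean in
   spectrum and label space): start from the most distant pair, then
   repeatedly add the sample whose minimum joint distance to the chosen
   set is largest. Deterministic; ties break to the lowest index, so the
   size-k set nests inside the size-k+1 set.

4. **Backbone.** A 1-D residual CNN implemented directly on NumPy
   (the environment used for this package provides no deep-learning
   framework; forward, backward, and the optimiser are explicit code):
   four stages of two basic blocks, each block two width-3 convolutions
   with batch normalisation and ReLU and an identity or projection
   shortcut; channels 64/128/256/512; the first convolution of each
   stage has stride 2; flatten; fully connected layers 512/128/64/32
   (ReLU) and a linear scalar output. Training: Adam (initial rate
   1e-3 full profile, 2e-3 test profile), MSE loss, batch size 5,
   learning-rate halving on plateau, early stopping. Labels are
   standardised internally and predictions mapped back. All randomness
   flows from one seed; runs are bit-reproducible.

5. **Transfer by fine-tuning.** The target backbone starts from the
   source weights; the first L main-path convolutions are frozen
   (projection shortcuts follow their block). The full-scale profile
   freezes L = 10 of 16; the desk-scale profile freezes 6 of 8 — with a
   shallow backbone the final block suffices for adaptation, and the
   longer shared frozen trunk keeps the source and target bottleneck
   spaces aligned, which matters because the boosted regressor pools
   features from both networks.

6. **Bottleneck + SVR.** Flatten-layer activations ("bottleneck
   features") from the source model (source samples) and the fine-tuned
   model (target samples) feed an RBF-kernel ε-SVR. Features are
   column-standardised with the fitting set's statistics. The
   hyperparameters (C, γ, ε; log-10 space, boxes C∈[1e-2,1e3],
   γ∈[1e-4,1e1], ε∈[1e-4,1]) are tuned by particle-swarm optimisation
   (swarm 50, 50 iterations, c1=1.5, c2=1.7, inertia 0.9→0.4, 10-fold
   CV RMSE objective; the desk profile shrinks this to 6 particles,
   5 iterations, 3 folds). For the boosted hybrid the CV objective is
   evaluated on the pooled source+target calibration features — the
   aggregate the boosted regressor actually fits; tuning on source
   features alone was observed to return degenerate γ whenever a source
   backbone happened to train poorly.

7. **Two-stage instance-transfer boosting.** Source and target
   calibration instances are pooled with one weight each, initialised
   uniformly. The outer loop runs K steps (default 10; desk profile
   3–4). Each step fits an AdaBoost.R2 ensemble on the pool with the
   current weights — *stage 2*: only target weights are re-distributed
   by the inner loop; the source block is frozen and the target block's
   total is preserved — and estimates its target-domain error by F-fold
   cross-validation over the target instances. *Stage 1* then
   down-weights every source instance by β^{e_i} (e_i its adjusted
   error from a weighted fit on the pool), with β found by binary
   search (tolerance 1e-10) so that the renormalised target share hits
   the schedule n/(m+n) + t/(K−1)·(1 − n/(m+n)) — the target share
   grows linearly to 1, so late steps are almost target-only. The
   returned model is the step ensemble with the smallest
   cross-validated error (ties to the earliest step); this argmin guard
   is what prevents negative transfer when the source does not help.
   Prediction is the AdaBoost.R2 weighted median of member predictions
   with member weights ln(1/β_t).

### Why the inner loop resamples

AdaBoost.R2 can pass the instance weights to the base learner or fit
each round on a weight-proportional bootstrap resample (the original
formulation, and what scikit-learn's `AdaBoostRegressor` does). With a
CV-tuned SVR and weight-passing, successive members are nearly
identical — measured member-prediction spread ≈ 5e-4 on a label with
standard deviation 0.11 — so the iteration count N is inert, while the
well-documented behaviour of this method family is that accuracy
improves with N up to a plateau. The resampling mode injects the
diversity the weighted median needs and reproduces that
benefit-then-plateau shape. Both modes are implemented:
`adaboost_r2_fit` defaults to weight-passing (so a 1-round ensemble is
exactly one weighted SVR fit, a convenient contract for testing), and
`TransferConfig.bootstrap=True` (the pipeline default) switches the
transfer stack to resampling.

## Baselines

- **PLSR**: centred PLS1 (SVD-based); component count picked by 10-fold
  CV RMSE over 1..20.
- **SBC**: ordinary least squares of reference values on master-model
  predictions over the transfer standards; corrected = slope·pred + bias.
- **PDS**: per-wavelength regression of the master column on the slave
  window [j−k, j+k] (default half-width 5, clipped at edges), ridge
  penalty 1e-6 for stability at narrow windows; the banded transform
  maps slave spectra into master space. Transfer standards are the
  SPXY-selected target calibration specimens, which in the paired
  synthetic design exist in both domains.

## The synthetic-data generator

No public reference dataset of paired multi-moisture wood spectra is
available, so every experiment runs on synthetic spectra built to
emulate that structure:

- Seven Gaussian absorption bands (centres 480–2270 nm, defaults near
  known O–H/C–H overtone regions) on a smooth instrument drift.
- Density ~ Uniform(0.4, 0.8) g/cm³; each band's amplitude is affine in
  density (coupling coefficients 0.05–0.45 AU per g/cm³).
- Specimen-level nuisance chemistry: per-band amplitude jitter
  (sd 0.05 AU), tied to the specimen and therefore identical across
  moisture levels, exactly like the density label. This caps the
  attainable R² and was set so a well-trained source model reaches
  R² ≈ 0.6–0.8 — the regime the method is reported to operate in.
- Moisture shift relative to the 10 % level: baseline offset
  (0.0015 AU/%), band-centre shift (0.04 nm/%), band broadening
  (0.0015 relative/%), and a water-band amplitude gain (0.008
  relative/% on the 1450 and 1940 nm bands). The water-band gain is the
  component that survives SNV and makes the domain gap a genuine shape
  change; without it a source model transfers almost unchanged.
- Per-sample multiplicative (sd 0.02) and additive (sd 0.01 AU) scatter
  and iid noise (sd 0.003 AU).

The same seed yields the same specimens (densities, jitter) at every
moisture level — the paired one-set-of-wood-many-conditions design —
while measurement noise is drawn independently per level. What the
generator does *not* model: radiative-transfer physics, instrument
response functions, wavelength-dependent noise, temperature effects, or
real wood anatomy. Passing trend tests on these spectra therefore shows
the pipeline behaves as designed under a controlled, plausible domain
shift; it is not evidence about any particular real instrument or
species.

## Problem sizes and profiles

Two bundled profiles (`nirtransfer.experiments`):

- `full_profile()` — the full-scale architecture and iteration
  counts (2151-point grid, 4-stage/16-conv backbone, PSO 50×50, K=10,
  N=50, F=10). Functional but hours of CPU per experiment.
- `test_profile()` — the desk scale all tests and the acceptance script
  use: 128-point grid, 2-stage/8-conv backbone (8/16 channels, FC
  32/16), 120 training epochs with a 15 % validation split for early
  stopping, PSO 6×5 with 3 folds, K=3, N=10, F=3, L=6 frozen. A full
  M-sweep over five data seeds runs in a few minutes.

Experiment repeats re-train the stochastic components with shifted
seeds on deterministic SPXY splits; reported target-domain numbers in
the trend tests are averaged over the three target moisture groups per
seed and summarised by the median across five seeds, with paired
per-seed differences used for method-vs-method comparisons.

## Numerical choices and degenerate inputs

- SNV refuses constant rows (named in the error); the 2-D correlation
  map zeroes constant-wavelength rows/columns with a warning instead of
  aborting.
- SPXY ties break to the lowest index; scaling the spectra by any
  positive constant leaves splits unchanged (normalised distances).
- Stage-1 binary search returns β=1 with a warning if the requested
  target share is already exceeded (source weights are never
  up-weighted), and uses the smallest attainable β if zero-error source
  instances make the share unreachable.
- A first inner-loop learner with weighted error ≥ 0.5 yields a
  single-member ensemble with a warning; β is capped below 1 so member
  weights stay positive. All-zero residuals stop the loop (perfect
  learner).
- Non-finite training loss aborts with a diagnostic rather than
  continuing silently.
- CSV round trips are bit-exact (shortest-repr floats on write,
  round-trip float parsing on read).

## Known limitations

- The backbone interpolates small calibration sets (training R² ≈ 0.99);
  generalisation then rests on early stopping and architecture, so
  individual fine-tuning runs carry noticeable variance. The experiment
  protocols average over repeats/groups for this reason.
- The boosting helps most when the domain gap is large and M moderate;
  with no gap it roughly matches a target-only SVR (the argmin-CV guard)
  rather than beating it.
- PDS assumes paired standards measured in both domains; with unpaired
  real data a pairing step would be needed upstream.
- The desk profile's coarse 128-point grid makes the few-nm band shifts
  sub-resolution; the shift component of the domain gap is only
  exercised at finer grids.
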