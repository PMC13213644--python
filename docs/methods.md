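# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the limits of what the test suite demonstrates.

## The generative reflectance model

Real inputs for this problem are ROI-mean reflectance spectra of powdered
root samples with HPLC reference concentrations, none publicly deposited.
The generator therefore simulates the physics the pre-processing chain is
designed for:

    R(λ) = a · B_c(λ) · exp(−Σ_k c_k ε_k(λ)) + b + ε_noise,  truncated to [0, 100] %

- **B_c(λ)** — smooth class baseline: a logistic rise from ~22 % at 427 nm to
  a plateau near 77 % with a mild downturn past 960 nm, matching the overall
  shape of powdered-root VIS-NIR reflectance. The old-root baseline is scaled
  to 0.78 of the tuberous curve (its reflectance is markedly lower at every
  band); taproot sits at 0.96 with a +2 % offset. Each class additionally
  carries pigment absorption Gaussians in the VIS region (tuberous 505 nm;
  taproot 548 nm; old root 468 + 642 nm, the darker oxidized coloration).
  Root classes differ visibly in color, and VIS-range spectral variation in
  real samples is dominated by exactly such chromophore differences; without
  them the generator would make taproot and old root differ only by a global
  scale factor, which no derivative-based classifier could (or should) use.
- **ε_k(λ)** — absorptivity of the three marker analytes
  (norisoboldine-, linderane-, lindenenol-like), each a sum of 2–3 Gaussian
  peaks strictly inside 427–994 nm with disjoint peak sets; amplitudes give
  absorbances of 0.1–0.5 at class-typical concentrations.
- **c_k** — log-normal concentrations (mg/g). Tuberous medians
  (2.0, 0.50, 2.5) strictly dominate taproot (0.8, 0.20, 1.0) and old root
  (0.7, 0.18, 0.9); taproot ≈ old root. Log-scale SD 0.35 gives realistic
  overlap between classes.
- **Scatter and noise** — multiplicative a ~ lognormal(0, 0.05), additive
  b ~ N(0, 0.5 %); per-band noise SD 0.1 %. The noise default reflects what
  the spectra represent: ROI means over thousands of pixels, where per-pixel
  detector noise averages down by orders of magnitude, leaving smooth curves.
- Default sample layout 87/30/30 (tuberous/taproot/old) and 270 bands on
  427–994 nm — the study conditions.

Hypercubes are built per pixel from the same model with
raw = D + (W − D)·R/100, spatially uniform per-band dark/white reference
vectors, and a near-dark (2 %) background signature, so black/white
calibration and threshold masking are exactly testable. Feature tables are
log-normal intensities (log-SD 0.4) with planted features elevated by the
configured fold change in one group (cycling through the three groups, with
the log-normal mean correction so the *arithmetic* group-mean ratio equals the
planted factor) and QC samples drawn around the grand mean at 15 % of the
sample variance.

What the generator does **not** emulate: instrument drift and wavelength
miscalibration, particle-size and moisture effects, correlated chemical
backgrounds beyond the three analytes, chromatographic artifacts in feature
tables (retention-time drift, ionization suppression), and spatial texture
within a sample. Passing tests therefore demonstrate algorithmic correctness
and recovery of planted structure under a faithful noise model — not
field performance on real roots.

## Wavelength selectors

**CARS** (default 50 runs, 80 % calibration fraction, max 14 latent
variables, 10-fold RMSECV). Run i keeps the top r_i fraction of surviving
bands by |PLS coefficient| — r_i = a·e^(−k·i) decaying from 1.0 at run 1 to
2/p at run N — then resamples survivors with coefficient-proportional
weights. The subset with minimal RMSECV across runs is returned. The
literature describing this study's settings mixes a "1000 runs" Monte Carlo
figure with "50 Monte Carlo samplings"; 50 sampling runs is the canonical
CARS loop and is the default here, with the run count exposed in
`CARSConfig` for the other reading.

**SPA** (m_max 50, SPXY test ratio 1/3, standardization on, F-test α 0.25).
Chains of successively most-orthogonal bands are grown from every start
band; candidate subsets are scored by PRESS of an MLR model on the SPXY
split; the smallest subset whose PRESS is not significantly worse than the
minimum under F(α, n_val, n_val) wins. SPXY is Kennard–Stone on the summed
max-normalized X and y distances, fully deterministic with index tie-breaks.

**Random frog** (2000 iterations, initial size Q = 2). Proposals resize the
current subset by a normal draw (SD 0.3·|V|); shrink moves keep the
highest-|PLS coefficient| members, grow moves draw a 3×-oversampled random
pool and trim it back by coefficient magnitude. Improving candidates are
always accepted; worse ones with probability 0.1·(RMSECV ratio) — the 0.1
damping (acceptance temperature) follows the original algorithm and is what
keeps the chain concentrated near informative subsets. A band's selection
probability is its frequency across chain states; the final subset is the
top-k by probability with k chosen by minimal RMSECV over k ∈ {2..30}
(a probability-threshold mode is available).

Coefficient ties everywhere break toward the lower band index, so all three
selectors are bit-reproducible under a fixed seed.

## Learners

- **LSSVM**: dual system [[0, 1ᵀ], [1, K + I/γ]]·[b; α] = [0; y], solved
  densely. The RBF kernel uses the *mean* squared band difference,
  K(u,v) = exp(−mean((u−v)²)/σ²), rather than the summed distance: with the
  summed convention, σ² = 2 on dozens of standardized bands collapses K to
  the identity and the model to the training mean. Normalizing by band count
  makes the width dimensionless in the number of retained bands, so the
  published γ = σ² = 2 is meaningful for any subset size. A linear kernel is
  available (and reduces to ridge/OLS at large γ, which the tests verify).
- **ELM**: input weights uniform(−1, 1), biases uniform(0, 1) (seeded),
  sigmoid hidden layer, minimum-norm least-squares output weights via
  pseudoinverse.
- **BPNN**: one sigmoid hidden layer (8 neurons), linear output, full-batch
  plain gradient descent at η = 0.6 for up to 1000 epochs or until the
  target MSE 1e−5; inputs and targets are standardized internally so that
  learning rate is stable, and the loss trajectory is recorded. Divergence
  (non-finite loss) raises with the epoch index.
- Classifiers ride on scikit-learn: multinomial logistic regression with
  C = 1e4 (an effectively unregularized fit), one-vs-rest RBF SVM, MLP with
  one 50-neuron hidden layer. Inputs are standardized with constants stored
  on the trained predictor.

A trained predictor freezes its pre-processing chain, band subset, band axis
and normalization constants; prediction on raw spectra replays that exact
path and refuses mismatched band axes.

## Evaluation conventions

- RMSE uses the 1/n denominator; R² is one minus the residual/total sum of
  squares ratio.
- RPD divides the *population* SD (n denominator) of the prediction
  partition's reference values by RMSEP. Partition and denominator are
  conventions the source descriptions leave open; both are fixed here and
  RPD·RMSE = SD holds to 1e−12 by construction.
- Multiclass precision/recall/F1 are one-vs-rest, macro-averaged by default
  (weighted averaging by flag); kappa uses Po = trace/total and
  Pe = Σ rowᵢ·colᵢ/total².
- Stratified splits allocate per class by largest-remainder rounding and are
  seeded; a 147-sample 60/20/20 split yields 87/30/30-style partitions but
  the exact per-class allocation rule is this package's own (the original
  cannot be reconstructed from published totals alone).

## Pre-processing conventions

- SNV uses the sample (n−1) SD and raises on constant spectra.
- Derivatives are SG derivative filters in units of reflectance per band
  index (not per nm); window 11, polyorder 3 by default — unstated in the
  source descriptions, chosen as common chemometric practice at ~270 bands
  and configurable everywhere.
- Hyphenated chain names apply left to right: "2ndD-SG" differentiates, then
  smooths. The reverse order and SNV-first combinations are expressible as
  explicit step lists; SNV-first is the default reading for SNV combinations.

## Metabolomics screen

Normalization (unspecified in vendor workflows) defaults to per-sample
median scaling; ANOVA runs on log2 intensities while fold changes are
computed on the raw normalized scale. For three groups FC is the maximum
pairwise ratio of group means — a convention choice, since multi-group FC is
not standardized. Both screen thresholds are strict inequalities (P < 0.05,
FC > 2.0), so a feature at exactly FC = 2.0 is excluded. Features with a
zero group mean have undefined FC and are reported separately. PLS-DA uses
mean-centered PLS2 against one-hot labels with 7-fold cross-validated
Q² = 1 − PRESS/SS.

## Mapping

Concentration maps are rendered at native cube resolution with a red (high)
to black (low) palette; background pixels render black; color bounds default
to the per-image foreground min/max with fixed global bounds available for
cross-sample comparison. Negative predictions render at the black endpoint
but are written to CSV unmodified. The PNG is produced by direct palette
mapping (byte-deterministic); the annotated colorbar is a separate companion
figure.

## Problem sizes

The defaults used by the tests and the acceptance script are the study-scale
conditions: 147 spectra × 270 bands for end-to-end classification and
quantification; a 100 × 270 design with 10 planted bands for CARS/random
frog (2000 frog iterations) and a 30 × 30 design with 3 planted bands for
SPA; 500-feature tables with 40 planted differentials (49 samples + 6 QC)
for the screen. The demo pipeline (`hsichem run`) uses a reduced frog
iteration count (300) as its default; all counts are configuration.

## Known limitations

- The LS-SVM kernel normalization (mean squared difference) is this
  package's convention; coefficients are not numerically comparable to
  implementations using the summed-distance convention.
- CARS subset sizes are only monotone in expectation — adaptive resampling
  can transiently shrink a subset below the EDF bound.
- The BPNN is plain gradient descent by design; it is the weakest learner
  here and can need many epochs on ill-conditioned targets.
- PLS-DA R²X is reported on the centered (unscaled) X; autoscaled variants
  will differ.
- The synthetic generator's realism limits are listed above; no claim is
  made about real-sample performance.
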